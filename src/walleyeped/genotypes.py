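"""Genotype containers and file I/O.

The substrate for the whole pipeline is a samples x loci matrix of diploid
biallelic genotype calls coded as alternate-allele dosage (0, 1, 2) with
missing calls stored as NaN. Loci may carry an amplicon id so that
per-amplicon thinning can be applied during quality control.

On disk the canonical format is a plain CSV with header
``sample_id,<locus_1>,...,<locus_L>`` and cells ``0|1|2`` or ``NA``; an
optional companion CSV maps each locus to its amplicon
(``locus_id,amplicon_id,ref,alt``). VCF import maps GT fields to dosages.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.nan

__all__ = [
    "GenotypeMatrix",
    "read_genotype_csv",
    "write_genotype_csv",
    "read_locus_map",
    "write_locus_map",
    "read_metadata",
    "write_metadata",
    "read_vcf",
]


@dataclass
class GenotypeMatrix:
    """Samples x loci diploid dosage matrix with missing calls as NaN.

    Parameters
    ----------
    sample_ids : list of str
        Row labels, unique.
    locus_ids : list of str
        Column labels, unique.
    calls : ndarray of float, shape (n_samples, n_loci)
        Values in {0, 1, 2, NaN}.
    amplicon_of : dict, optional
        Maps locus id -> amplicon id; loci sharing an amplicon are candidates
        for per-amplicon thinning.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray
    amplicon_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("duplicate locus ids")
        valid = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = np.unique(self.calls[~valid])
            raise ValueError(f"genotype calls outside {{0,1,2,NA}}: {bad}")

    # -- basic views ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def row(self, sample_id: str) -> np.ndarray:
        return self.calls[self.sample_index(sample_id)]

    def subset(
        self,
        samples: list[str] | None = None,
        loci: list[str] | None = None,
    ) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given samples/loci (order kept)."""
        if samples is None:
            samples = self.sample_ids
        if loci is None:
            loci = self.locus_ids
        si = [self.sample_ids.index(s) for s in samples]
        li = [self.locus_ids.index(l) for l in loci]
        amp = {l: self.amplicon_of[l] for l in loci if l in self.amplicon_of}
        return GenotypeMatrix(list(samples), list(loci), self.calls[np.ix_(si, li)], amp)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.sample_ids, columns=self.locus_ids)

    def equal(self, other: "GenotypeMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.calls, other.calls, equal_nan=True)
        )


# -- CSV round trip ----------------------------------------------------


def read_genotype_csv(path: str, locus_map: str | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col="sample_id", na_values=["NA"], dtype=str)
    calls = df.astype(float).to_numpy()
    amp: dict[str, str] = {}
    if locus_map is not None:
        amp = read_locus_map(locus_map)
    return GenotypeMatrix(
        [str(s) for s in df.index], [str(c) for c in df.columns], calls, amp
    )


def write_genotype_csv(gm: GenotypeMatrix, path: str, overwrite: bool = False) -> None:
    _guard_overwrite(path, overwrite)
    df = gm.to_frame()
    # integer-looking cells, NA for missing
    out = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.index.name = "sample_id"
    out.to_csv(path)


def read_locus_map(path: str) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    return dict(zip(df["locus_id"], df["amplicon_id"]))


def write_locus_map(
    gm: GenotypeMatrix, path: str, overwrite: bool = False
) -> None:
    _guard_overwrite(path, overwrite)
    rows = [
        {"locus_id": l, "amplicon_id": gm.amplicon_of.get(l, l), "ref": "A", "alt": "G"}
        for l in gm.locus_ids
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# -- fish metadata -----------------------------------------------------

METADATA_COLUMNS = ["fish_id", "year", "stage", "sex", "length_mm", "age", "sampled"]


def read_metadata(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"fish_id": str, "stage": str, "sex": str},
        na_values=["NA"],
    )
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return df


def write_metadata(df: pd.DataFrame, path: str, overwrite: bool = False) -> None:
    _guard_overwrite(path, overwrite)
    df.to_csv(path, index=False, na_rep="NA")


# -- VCF import --------------------------------------------------------


def read_vcf(path: str) -> GenotypeMatrix:
    """Import a VCF, mapping diploid GT fields to 0/1/2 dosage.

    Multiallelic records are skipped; missing or half-called genotypes map to
    NA. The locus id is ``CHROM:POS`` and the amplicon id is CHROM, which
    matches amplicon-panel VCFs where each amplicon is a contig.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    locus_ids: list[str] = []
    amp: dict[str, str] = {}
    cols: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        lid = f"{rec.CHROM}:{rec.POS}"
        gts = rec.genotype.array()[:, :2].astype(float)
        gts[gts < 0] = np.nan
        dosage = gts.sum(axis=1)
        locus_ids.append(lid)
        amp[lid] = rec.CHROM
        cols.append(dosage)
    calls = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return GenotypeMatrix(samples, locus_ids, calls, amp)


def _guard_overwrite(path: str, overwrite: bool) -> None:
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
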