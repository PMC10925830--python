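"""Truth-known population simulator for a lake walleye parentage study.

Generates an adult population with sex, age, growth percentile and length,
an annual breeding process with configurable female effects on offspring
survival, Mendelian genotype transmission over a biallelic SNP panel, and a
multi-year survey that samples spawning adults in spring and age-0/age-1
juveniles in fall. Every downstream stage of the pipeline (QC, parentage,
pedigree accumulation, reproductive-success models) can therefore be tested
against known truth.

Design of the breeding process
------------------------------
Each study year, every alive mature female produces at least one surviving
age-0 offspring with probability

    inv_logit(intercept + b_len * z(TL) + b_growth * percentile + year_effect)

A successful female draws a number of mates from a zero-truncated Poisson
whose *mean* equals ``mate_count_mean`` (the rate is solved numerically), and
an offspring count ``max(n_mates, 1 + Poisson(extra_offspring_mean))``
distributed round-robin among the mates so that every drawn mate fathers at
least one offspring. Mates are drawn uniformly from alive mature males, so a
male can appear in several females' mate sets within and across years.

Defaults reproduce the study conditions: ~1300 adults over four cohorts
(2017-2020), a ~300-locus panel, 19.8 % annual natural mortality, mean mate
counts near 1.4, and a strong positive year effect in the second study year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, ndtri

from .genotypes import (
    GenotypeMatrix,
    write_genotype_csv,
    write_locus_map,
    write_metadata,
    _guard_overwrite,
)

__all__ = ["SimConfig", "TruthSet", "simulate_population", "write_dataset"]

# von Bertalanffy growth used for mean total length at age; females grow to
# longer asymptotic lengths than males in this species.
VB_LINF = {"F": 560.0, "M": 480.0}
VB_K = 0.25
VB_T0 = -0.5
LENGTH_CV = 0.08  # fixed CV mapping growth percentile -> length offset


@dataclass
class SimConfig:
    """Study-design parameters for the population and survey simulator."""

    n_adults: int = 2000
    n_loci: int = 300
    years: tuple[int, ...] = (2017, 2018, 2019, 2020)
    allele_freq_range: tuple[float, float] = (0.2, 0.8)
    genotyping_error_rate: float = 0.01
    missing_rate: float = 0.03
    contamination_fraction: float = 0.025
    duplicate_fraction: float = 0.067
    annual_mortality: float = 0.198
    success_intercept: float = -1.73
    female_length_effect: float = 0.0
    female_growth_effect: float = 0.676
    year_effects: tuple[float, ...] = (0.0, 1.2, 0.0, 0.2)
    mate_count_mean: float = 1.4
    extra_offspring_mean: float = 0.4
    adult_capture_prob: float = 0.35
    juvenile_capture_prob: float = 0.8
    age1_capture_prob: float = 0.30
    adult_capture_years: tuple[int, ...] | None = None  # default: all but last year
    unknown_sex_fraction: float = 0.045
    min_age: int = 3
    max_age: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "genotyping_error_rate": self.genotyping_error_rate,
            "missing_rate": self.missing_rate,
            "contamination_fraction": self.contamination_fraction,
            "duplicate_fraction": self.duplicate_fraction,
            "annual_mortality": self.annual_mortality,
            "adult_capture_prob": self.adult_capture_prob,
            "juvenile_capture_prob": self.juvenile_capture_prob,
            "age1_capture_prob": self.age1_capture_prob,
            "unknown_sex_fraction": self.unknown_sex_fraction,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} not a probability")
        if self.n_loci < 50:
            raise ValueError("n_loci >= 50 required for parentage power")
        years = tuple(self.years)
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("years must be strictly increasing")
        if len(self.year_effects) != len(years):
            raise ValueError("year_effects must align with years")
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("allele_freq_range must lie inside (0,1)")
        if self.mate_count_mean < 1.0:
            raise ValueError("mate_count_mean must be >= 1")
        # warn (not fail) on degenerate survival probabilities
        lp = (
            self.success_intercept
            + np.array(self.year_effects)[:, None]
            + np.array([0.0, self.female_growth_effect])[None, :]
        )
        p = expit(lp)
        if p.max() <= 1e-12 or p.min() >= 1 - 1e-12:
            warnings.warn("offspring survival probability is degenerate (always 0 or 1)")

    @property
    def capture_years(self) -> tuple[int, ...]:
        """Years with a spring adult survey (default: all but the last year,
        mirroring a study design where the final spring survey was missed)."""
        if self.adult_capture_years is not None:
            return tuple(self.adult_capture_years)
        return tuple(self.years[:-1])


@dataclass
class TruthSet:
    """Ground truth for recovery tests."""

    pedigree: pd.DataFrame  # offspring_id, mother_id, father_id, cohort_year
    alive: pd.DataFrame  # adults x years booleans
    success: pd.DataFrame  # adults x years booleans (>=1 surviving offspring)
    spawner_counts: dict[int, int]  # per-year distinct successful parents
    founder_allele_freqs: np.ndarray
    adults: pd.DataFrame  # fish_id, sex, age0_year ages, growth percentile, ...
    true_genotypes: pd.DataFrame  # individual x locus true dosages

    def mates_per_parent(self, sex: str | None = None) -> pd.DataFrame:
        """True distinct-mate counts per successful parent per cohort year."""
        ped = self.pedigree
        rows = []
        for (year,), grp in ped.groupby(["cohort_year"]):
            for col, other in (("mother_id", "father_id"), ("father_id", "mother_id")):
                for pid, sub in grp.groupby(col):
                    rows.append(
                        {
                            "parent_id": pid,
                            "year": year,
                            "role": "mother" if col == "mother_id" else "father",
                            "n_mates": sub[other].nunique(),
                        }
                    )
        out = pd.DataFrame(rows)
        if sex == "F":
            out = out[out.role == "mother"]
        elif sex == "M":
            out = out[out.role == "father"]
        return out.reset_index(drop=True)


def _ztp_lambda(mean: float) -> float:
    """Rate of a zero-truncated Poisson with the given mean (mean > 1)."""
    if mean <= 1.0 + 1e-9:
        return 0.0
    return brentq(lambda lam: lam / (1 - np.exp(-lam)) - mean, 1e-9, 50.0)


def _sample_ztp(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson draws by rejection (lam modest here)."""
    if lam <= 0.0:
        return np.ones(size, dtype=int)
    out = rng.poisson(lam, size)
    bad = out == 0
    while bad.any():
        out[bad] = rng.poisson(lam, bad.sum())
        bad = out == 0
    return out


def mean_length_at_age(age: np.ndarray, sex: np.ndarray) -> np.ndarray:
    linf = np.where(np.asarray(sex) == "F", VB_LINF["F"], VB_LINF["M"])
    return linf * (1 - np.exp(-VB_K * (np.asarray(age, dtype=float) - VB_T0)))


def length_at_age(age: np.ndarray, sex: np.ndarray, percentile: np.ndarray) -> np.ndarray:
    """Mean length at age shifted by the normal quantile of the growth percentile."""
    z = ndtri(np.clip(percentile, 1e-9, 1 - 1e-9))
    return mean_length_at_age(age, sex) * (1 + LENGTH_CV * z)


def _hwe_draw(rng: np.random.Generator, freqs: np.ndarray, n: int) -> np.ndarray:
    """n x L dosage draws at Hardy-Weinberg proportions."""
    return (
        (rng.random((n, freqs.size)) < freqs).astype(np.int8)
        + (rng.random((n, freqs.size)) < freqs).astype(np.int8)
    ).astype(float)


def _mendelian_offspring(
    rng: np.random.Generator, mother: np.ndarray, father: np.ndarray
) -> np.ndarray:
    """One gamete from each parent; heterozygotes transmit alt w.p. 1/2."""
    pm = mother / 2.0
    pf = father / 2.0
    return (
        (rng.random(mother.size) < pm).astype(float)
        + (rng.random(father.size) < pf).astype(float)
    )


def simulate_population(
    config: SimConfig,
) -> tuple[TruthSet, pd.DataFrame, GenotypeMatrix]:
    """Simulate adults, breeding, genotypes and the survey.

    Returns
    -------
    truth : TruthSet
    metadata : DataFrame
        One row per capture event: fish_id, year, stage, sex, length_mm,
        age, sampled.
    genotypes : GenotypeMatrix
        Observed (error + missingness + contamination + duplicates) calls for
        every genotyped individual.
    """
    rng = np.random.default_rng(config.seed)
    years = list(config.years)
    n = config.n_adults

    # ---- adults ------------------------------------------------------
    adult_ids = [f"A{i:05d}" for i in range(n)]
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    age_y0 = rng.integers(config.min_age, config.max_age + 1, n)
    growth_pct = rng.random(n)

    # ---- survival ----------------------------------------------------
    alive = np.ones((n, len(years)), dtype=bool)
    for j in range(1, len(years)):
        surv = rng.random(n) < (1 - config.annual_mortality)
        alive[:, j] = alive[:, j - 1] & surv

    # ---- founder genotypes ------------------------------------------
    lo, hi = config.allele_freq_range
    freqs = rng.uniform(lo, hi, config.n_loci)
    locus_ids = [f"L{k:04d}" for k in range(config.n_loci)]
    adult_geno = _hwe_draw(rng, freqs, n)

    # ---- breeding ----------------------------------------------------
    lam_mates = _ztp_lambda(config.mate_count_mean)
    ped_rows = []
    off_geno: list[np.ndarray] = []
    off_ids: list[str] = []
    off_cohort: list[int] = []
    success = np.zeros((n, len(years)), dtype=bool)
    female_idx = np.flatnonzero(sex == "F")
    male_idx = np.flatnonzero(sex == "M")
    lp_year = np.array(config.year_effects)
    for j, year in enumerate(years):
        females = female_idx[alive[female_idx, j]]
        males = male_idx[alive[male_idx, j]]
        if females.size == 0 or males.size == 0:
            continue
        tl = length_at_age(age_y0[females] + j, sex[females], growth_pct[females])
        z_tl = (tl - tl.mean()) / max(tl.std(), 1e-9)
        lp = (
            config.success_intercept
            + config.female_growth_effect * growth_pct[females]
            + config.female_length_effect * z_tl
            + lp_year[j]
        )
        ok = rng.random(females.size) < expit(lp)
        winners = females[ok]
        n_mates = _sample_ztp(rng, lam_mates, winners.size)
        for fi, m in zip(winners, n_mates):
            m = int(min(m, males.size))
            mates = rng.choice(males, size=m, replace=False)
            n_off = max(m, 1 + rng.poisson(config.extra_offspring_mean))
            for k in range(n_off):
                dad = mates[k % m]
                oid = f"J{year}_{len(off_ids):05d}"
                off_ids.append(oid)
                off_cohort.append(year)
                off_geno.append(
                    _mendelian_offspring(rng, adult_geno[fi], adult_geno[dad])
                )
                ped_rows.append(
                    {
                        "offspring_id": oid,
                        "mother_id": adult_ids[fi],
                        "father_id": adult_ids[dad],
                        "cohort_year": year,
                    }
                )
            success[fi, j] = True
            for dad in mates[: min(m, n_off)]:
                success[dad, j] = True

    pedigree = pd.DataFrame(
        ped_rows, columns=["offspring_id", "mother_id", "father_id", "cohort_year"]
    )
    spawner_counts = {
        int(y): int(
            pd.unique(
                pd.concat(
                    [
                        pedigree.loc[pedigree.cohort_year == y, "mother_id"],
                        pedigree.loc[pedigree.cohort_year == y, "father_id"],
                    ]
                )
            ).size
        )
        for y in years
    }

    # ---- offspring survival to age 1 --------------------------------
    n_off = len(off_ids)
    off_alive_age1 = rng.random(n_off) < (1 - config.annual_mortality)

    # ---- survey ------------------------------------------------------
    unknown_sex = rng.random(n) < config.unknown_sex_fraction
    meta_rows = []
    sampled_adult = np.zeros(n, dtype=bool)
    for j, year in enumerate(years):
        if year not in config.capture_years:
            continue
        caught = alive[:, j] & (rng.random(n) < config.adult_capture_prob)
        for i in np.flatnonzero(caught):
            sampled_adult[i] = True
            age = int(age_y0[i] + j)
            meta_rows.append(
                {
                    "fish_id": adult_ids[i],
                    "year": year,
                    "stage": "adult",
                    "sex": "U" if unknown_sex[i] else sex[i],
                    "length_mm": round(
                        float(length_at_age(age, sex[i], growth_pct[i])), 1
                    ),
                    "age": age,
                    "sampled": True,
                }
            )

    sampled_off = np.zeros(n_off, dtype=bool)
    for k, (oid, cohort) in enumerate(zip(off_ids, off_cohort)):
        if rng.random() < config.juvenile_capture_prob:
            sampled_off[k] = True
            tl0 = float(np.clip(rng.normal(140.0, 25.0), 60.0, 190.0))
            meta_rows.append(
                {
                    "fish_id": oid,
                    "year": cohort,
                    "stage": "age0",
                    "sex": "U",
                    "length_mm": round(tl0, 1),
                    "age": 0,
                    "sampled": True,
                }
            )
        elif (
            cohort + 1 in years
            and off_alive_age1[k]
            and rng.random() < config.age1_capture_prob
        ):
            sampled_off[k] = True
            tl1 = float(np.clip(rng.normal(230.0, 20.0), 191.0, 275.0))
            meta_rows.append(
                {
                    "fish_id": oid,
                    "year": cohort + 1,
                    "stage": "age1",
                    "sex": "U",
                    "length_mm": round(tl1, 1),
                    "age": 1,
                    "sampled": True,
                }
            )

    metadata = pd.DataFrame(meta_rows, columns=["fish_id", "year", "stage", "sex",
                                                "length_mm", "age", "sampled"])

    # ---- observed genotypes -----------------------------------------
    geno_ids = [adult_ids[i] for i in np.flatnonzero(sampled_adult)] + [
        off_ids[k] for k in np.flatnonzero(sampled_off)
    ]
    true_rows = np.vstack(
        [adult_geno[np.flatnonzero(sampled_adult)]]
        + ([np.vstack([off_geno[k] for k in np.flatnonzero(sampled_off)])]
           if sampled_off.any() else [])
    ) if sampled_adult.any() else np.vstack([off_geno[k] for k in np.flatnonzero(sampled_off)])
    calls = true_rows.copy()
    ng = calls.shape[0]

    # contamination: mix with another genotyped individual; loci where the two
    # genotypes differ read as heterozygous
    n_contam = int(round(config.contamination_fraction * ng))
    contam_idx = rng.choice(ng, size=n_contam, replace=False) if n_contam else np.array([], int)
    for i in contam_idx:
        other = int(rng.integers(ng))
        mixed = calls[i].copy()
        diff = calls[i] != calls[other]
        mixed[diff] = 1.0
        calls[i] = mixed

    # per-call genotyping error: replace with an independent HWE draw
    if config.genotyping_error_rate > 0:
        err = rng.random(calls.shape) < config.genotyping_error_rate
        redraw = _hwe_draw(rng, freqs, ng)
        calls[err] = redraw[err]

    # missingness
    if config.missing_rate > 0:
        calls[rng.random(calls.shape) < config.missing_rate] = np.nan

    # duplicates: exact copies of observed calls under new ids
    n_dup = int(round(config.duplicate_fraction * ng))
    dup_src = rng.choice(ng, size=n_dup, replace=False) if n_dup else np.array([], int)
    dup_ids = [f"{geno_ids[i]}_dup" for i in dup_src]
    if n_dup:
        calls = np.vstack([calls, calls[dup_src]])
    all_ids = geno_ids + dup_ids

    gm = GenotypeMatrix(
        all_ids, locus_ids, calls, {l: l for l in locus_ids}
    )

    adults = pd.DataFrame(
        {
            "fish_id": adult_ids,
            "sex": sex,
            "age_first_year": age_y0,
            "growth_percentile": growth_pct,
            "sampled": sampled_adult,
            "unknown_sex": unknown_sex,
        }
    )
    truth = TruthSet(
        pedigree=pedigree,
        alive=pd.DataFrame(alive, index=adult_ids, columns=years),
        success=pd.DataFrame(success, index=adult_ids, columns=years),
        spawner_counts=spawner_counts,
        founder_allele_freqs=freqs,
        adults=adults,
        true_genotypes=pd.DataFrame(
            np.vstack([adult_geno] + ([np.vstack(off_geno)] if off_geno else [])),
            index=adult_ids + off_ids,
            columns=locus_ids,
        ),
    )
    return truth, metadata, gm


def write_dataset(
    truth: TruthSet,
    metadata: pd.DataFrame,
    genotypes: GenotypeMatrix,
    out_dir: str,
    overwrite: bool = False,
) -> dict[str, str]:
    """Write the simulated dataset as plain CSVs; refuses to overwrite
    existing files unless told to. Returns the mapping of artifact -> path."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "genotypes": os.path.join(out_dir, "genotypes.csv"),
        "loci": os.path.join(out_dir, "loci.csv"),
        "metadata": os.path.join(out_dir, "metadata.csv"),
        "pedigree": os.path.join(out_dir, "pedigree.csv"),
        "alive": os.path.join(out_dir, "alive.csv"),
    }
    for p in paths.values():
        _guard_overwrite(p, overwrite)
    write_genotype_csv(genotypes, paths["genotypes"], overwrite=True)
    write_locus_map(genotypes, paths["loci"], overwrite=True)
    write_metadata(metadata, paths["metadata"], overwrite=True)
    truth.pedigree.to_csv(paths["pedigree"], index=False)
    truth.alive.rename_axis("fish_id").to_csv(paths["alive"])
    return paths
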