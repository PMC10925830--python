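"""Five-stage SNP panel quality control with linkage thinning.

Stage order (single pass; statistics are computed on the matrix as it stands
when a stage runs and earlier stages are never revisited):

1. remove loci genotyped in < 80 % of samples;
2. remove loci whose per-locus inbreeding coefficient |F_IS| exceeds 0.08
   (monomorphic loci, where F_IS is undefined, are removed here too and
   flagged — they are uninformative for parentage);
3. remove samples genotyped at < 80 % of loci;
4. remove samples with a contamination score > 0.4;
5. remove duplicate samples (identical calls at > 90 % of co-called loci),
   keeping one member of each duplicate group at random;
then linkage thinning: keep one SNP per amplicon, then repeatedly drop one
member of any locus pair whose standardized index of association exceeds
0.25.

F_IS is estimated as 1 - Ho/He with He = 2 p(1-p) from the called genotypes
(no small-sample correction). The contamination score is a standardized
heterozygosity excess, 1 - E[het]/observed het over the sample's called
loci, clamped to [-1, 1]; mixed-template samples read heterozygous wherever
the two templates differ, so their observed het count exceeds the
Hardy-Weinberg expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .genotypes import GenotypeMatrix

__all__ = [
    "QCThresholds",
    "QCReport",
    "compute_locus_stats",
    "compute_sample_stats",
    "filter_loci",
    "filter_samples",
    "find_duplicates",
    "pairwise_rbar_d",
    "rbar_d_matrix",
    "thin_linkage",
    "run_qc",
]

REMOVAL_REASONS = (
    "locus_call_rate",
    "fis",
    "sample_call_rate",
    "contamination",
    "duplicate",
    "amplicon_thin",
    "linkage_thin",
)


@dataclass
class QCThresholds:
    min_locus_call_rate: float = 0.80
    max_abs_fis: float = 0.08
    min_sample_call_rate: float = 0.80
    max_contamination: float = 0.40
    dup_identity: float = 0.90
    max_rbar_d: float = 0.25


@dataclass
class QCReport:
    """Accounting of what each stage removed and why."""

    thresholds: QCThresholds
    seed: int
    retained: GenotypeMatrix
    removed: list[dict] = field(default_factory=list)  # {id, kind, reason, stage}
    notes: list[str] = field(default_factory=list)

    def removed_ids(self, reason: str | None = None) -> list[str]:
        return [
            r["id"] for r in self.removed if reason is None or r["reason"] == reason
        ]

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(self.removed, columns=["id", "kind", "reason", "stage"])
        return df.groupby(["stage", "reason"], sort=False).size().rename("n").reset_index()

    def to_dict(self) -> dict:
        return {
            "thresholds": vars(self.thresholds),
            "seed": self.seed,
            "removed": self.removed,
            "notes": self.notes,
            "n_samples_retained": self.retained.n_samples,
            "n_loci_retained": self.retained.n_loci,
        }


# -- per-locus and per-sample statistics -------------------------------


def compute_locus_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Call rate, alt-allele frequency, Ho, He and F_IS per locus.

    F_IS = 1 - Ho/He; loci with He = 0 are flagged monomorphic and get
    F_IS = 0 with the flag set.
    """
    calls = gm.calls
    called = ~np.isnan(calls)
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore"):
        call_rate = n_called / calls.shape[0]
        p_hat = np.nansum(calls, axis=0) / (2 * np.maximum(n_called, 1))
        ho = (calls == 1).sum(axis=0) / np.maximum(n_called, 1)
    he = 2 * p_hat * (1 - p_hat)
    mono = he == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        fis = np.where(mono, 0.0, 1 - ho / np.where(mono, 1.0, he))
    df = pd.DataFrame(
        {
            "locus_id": gm.locus_ids,
            "call_rate": call_rate,
            "p_hat": p_hat,
            "Ho": ho,
            "He": he,
            "f_is": fis,
            "monomorphic": mono,
            "no_calls": n_called == 0,
        }
    ).set_index("locus_id")
    return df


def compute_sample_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Call rate, het rate and contamination score per sample.

    contamination_score = 1 - (expected het count)/(observed het count)
    where the expectation sums per-locus He over the sample's called loci;
    clamped to [-1, 1]; samples with zero observed hets score -1.
    """
    calls = gm.calls
    called = ~np.isnan(calls)
    locus = compute_locus_stats(gm)
    he = locus["He"].to_numpy()
    n_called = called.sum(axis=1)
    obs_het = (calls == 1).sum(axis=1)
    exp_het = (called * he[None, :]).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(obs_het > 0, 1 - exp_het / np.maximum(obs_het, 1), -1.0)
    score = np.clip(score, -1.0, 1.0)
    return pd.DataFrame(
        {
            "sample_id": gm.sample_ids,
            "call_rate": n_called / max(calls.shape[1], 1),
            "het_rate": obs_het / np.maximum(n_called, 1),
            "contamination_score": score,
        }
    ).set_index("sample_id")


# -- filtering stages --------------------------------------------------


def filter_loci(
    gm: GenotypeMatrix,
    min_call_rate: float = 0.80,
    max_abs_fis: float = 0.08,
) -> tuple[GenotypeMatrix, list[dict]]:
    """Locus call-rate filter, then |F_IS| filter (monomorphic removed, reason
    'fis'). F_IS exactly at the threshold is retained (strict inequality)."""
    stats = compute_locus_stats(gm)
    removed: list[dict] = []
    keep = []
    low_cr = stats["call_rate"] < min_call_rate
    for lid in gm.locus_ids:
        if low_cr[lid]:
            removed.append(
                {"id": lid, "kind": "locus", "reason": "locus_call_rate", "stage": 1}
            )
        else:
            keep.append(lid)
    gm1 = gm.subset(loci=keep)
    stats1 = stats.loc[keep]
    keep2 = []
    fis_active = np.isfinite(max_abs_fis)  # an infinite bound disables the stage
    for lid in keep:
        bad = fis_active and (
            abs(stats1.at[lid, "f_is"]) > max_abs_fis
            or bool(stats1.at[lid, "monomorphic"])
        )
        if bad:
            removed.append({"id": lid, "kind": "locus", "reason": "fis", "stage": 2})
        else:
            keep2.append(lid)
    out = gm1.subset(loci=keep2)
    if out.n_loci == 0:
        raise ValueError("locus filtering removed every locus")
    return out, removed


def filter_samples(
    gm: GenotypeMatrix,
    min_call_rate: float = 0.80,
    max_contamination: float = 0.40,
) -> tuple[GenotypeMatrix, list[dict]]:
    """Sample call-rate filter, then contamination-score filter (> threshold
    removed, strict)."""
    stats = compute_sample_stats(gm)
    removed: list[dict] = []
    keep = []
    for sid in gm.sample_ids:
        if stats.at[sid, "call_rate"] < min_call_rate:
            removed.append(
                {"id": sid, "kind": "sample", "reason": "sample_call_rate", "stage": 3}
            )
        else:
            keep.append(sid)
    gm1 = gm.subset(samples=keep)
    stats1 = compute_sample_stats(gm1)
    keep2 = []
    for sid in keep:
        if stats1.at[sid, "contamination_score"] > max_contamination:
            removed.append(
                {"id": sid, "kind": "sample", "reason": "contamination", "stage": 4}
            )
        else:
            keep2.append(sid)
    out = gm.subset(samples=keep2)
    if out.n_samples == 0:
        raise ValueError("sample filtering removed every sample")
    return out, removed


def _identity_matrix(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise (matching calls / co-called loci, co-called count)."""
    called = ~np.isnan(calls)
    x = np.nan_to_num(calls, nan=-9.0)
    n = calls.shape[0]
    match = np.zeros((n, n))
    co = np.zeros((n, n))
    # genotype one-hot trick: matches = sum over g of (calls==g)(calls==g)^T
    for g in (0.0, 1.0, 2.0):
        ind = (x == g).astype(float)
        match += ind @ ind.T
    c = called.astype(float)
    co = c @ c.T
    return match, co


def find_duplicates(
    gm: GenotypeMatrix,
    min_identity: float = 0.90,
    seed: int = 0,
    min_co_called: int = 20,
) -> tuple[list[list[str]], dict[str, str]]:
    """Duplicate groups (connected components of the > min_identity graph)
    and the seeded-random retained representative per group.

    Pairs with fewer than ``min_co_called`` co-called loci have undefined
    identity and are treated as non-duplicates (with a warning).
    """
    if gm.n_samples < 2:
        return [], {}
    match, co = _identity_matrix(gm.calls)
    with np.errstate(invalid="ignore", divide="ignore"):
        identity = match / co
    usable = co >= min_co_called
    if (~usable & (co > 0)).any():
        warnings.warn("some sample pairs have too few co-called loci; "
                      "identity undefined, treated as non-duplicate")
    adj = (identity > min_identity) & usable
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    rng = np.random.default_rng(seed)
    groups: list[list[str]] = []
    kept: dict[str, str] = {}
    for comp in range(n_comp):
        members = [gm.sample_ids[i] for i in np.flatnonzero(labels == comp)]
        if len(members) < 2:
            continue
        groups.append(members)
        kept[members[int(rng.integers(len(members)))]] = "retained"
    return groups, kept


# -- standardized index of association ---------------------------------


def _pair_moments(joint: np.ndarray) -> float:
    """r_bar_d from a 3x3 joint genotype count table of co-called samples.

    Pairwise individual distances at a locus are |g_i - g_j|; the statistic is
    the Pearson correlation of the two loci's distance vectors over all
    unordered sample pairs. With categorical dosages the pair sums reduce to
    sums over the joint table, so no explicit pair enumeration is needed.
    """
    n = joint.sum()
    if n < 2:
        return np.nan
    u = np.arange(3.0)
    dmat = np.abs(u[:, None] - u[None, :])  # |u - u'|
    ca = joint.sum(axis=1)
    cb = joint.sum(axis=0)
    n_pairs = n * (n - 1) / 2.0
    # sums over ordered pairs (i=j terms contribute zero distance)
    s_a = (ca[:, None] * ca[None, :] * dmat).sum() / 2.0
    s_b = (cb[:, None] * cb[None, :] * dmat).sum() / 2.0
    s_aa = (ca[:, None] * ca[None, :] * dmat**2).sum() / 2.0
    s_bb = (cb[:, None] * cb[None, :] * dmat**2).sum() / 2.0
    # joint sum: over ordered pairs of cells
    j = joint
    s_ab = np.einsum("ij,kl,ik,jl->", j, j, dmat, dmat) / 2.0
    var_a = s_aa / n_pairs - (s_a / n_pairs) ** 2
    var_b = s_bb / n_pairs - (s_b / n_pairs) ** 2
    if var_a <= 0 or var_b <= 0:
        return 0.0
    cov = s_ab / n_pairs - (s_a / n_pairs) * (s_b / n_pairs)
    return float(cov / np.sqrt(var_a * var_b))


def pairwise_rbar_d(
    gm: GenotypeMatrix, locus_a: str, locus_b: str, min_pairs: int = 2
) -> float:
    """Standardized index of association for one locus pair.

    Computed over all sample pairs co-called at both loci; returns 0 when
    either locus has zero distance variance (with a warning), and NaN when
    there are too few co-called samples.
    """
    a = gm.calls[:, gm.locus_ids.index(locus_a)]
    b = gm.calls[:, gm.locus_ids.index(locus_b)]
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < min_pairs:
        warnings.warn(f"too few co-called samples for {locus_a},{locus_b}")
        return np.nan
    joint = np.zeros((3, 3))
    for u in range(3):
        for v in range(3):
            joint[u, v] = np.sum((a[ok] == u) & (b[ok] == v))
    r = _pair_moments(joint)
    if r == 0.0:
        warnings.warn(f"zero distance variance for pair {locus_a},{locus_b}")
    return r


def rbar_d_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """All pairwise r_bar_d values, vectorized through per-pair 3x3 joint
    genotype tables built from one-hot matrix products."""
    calls = gm.calls
    L = calls.shape[1]
    onehot = [np.nan_to_num((calls == g).astype(float)) for g in (0.0, 1.0, 2.0)]
    joint = np.zeros((L, L, 3, 3))
    for u in range(3):
        for v in range(3):
            joint[:, :, u, v] = onehot[u].T @ onehot[v]
    out = np.full((L, L), np.nan)
    for i in range(L):
        for j in range(i + 1, L):
            r = _pair_moments(joint[i, j])
            out[i, j] = out[j, i] = r
    return out


def thin_linkage(
    gm: GenotypeMatrix, max_rbar_d: float = 0.25
) -> tuple[GenotypeMatrix, list[dict]]:
    """Per-amplicon thinning, then greedy pairwise association thinning.

    Per amplicon the SNP with the highest call rate is retained (ties broken
    by higher minor-allele frequency, then lexicographically smaller id).
    Then, taking pairs in decreasing r_bar_d order, while any pair exceeds the
    threshold the member with the lower call rate is removed (same tie rule,
    the lexicographically larger id goes).
    """
    removed: list[dict] = []
    stats = compute_locus_stats(gm)
    maf = np.minimum(stats["p_hat"], 1 - stats["p_hat"])

    def rank(lid: str) -> tuple:
        # higher is better: call rate, then MAF, then earlier id
        return (stats.at[lid, "call_rate"], maf[lid], [-ord(c) for c in lid])

    if gm.amplicon_of:
        by_amp: dict[str, list[str]] = {}
        for lid in gm.locus_ids:
            by_amp.setdefault(gm.amplicon_of.get(lid, lid), []).append(lid)
        keep = []
        for amp, members in by_amp.items():
            best = max(members, key=rank)
            keep.append(best)
            for lid in members:
                if lid != best:
                    removed.append(
                        {"id": lid, "kind": "locus", "reason": "amplicon_thin",
                         "stage": 6}
                    )
        keep = [l for l in gm.locus_ids if l in set(keep)]
        gm = gm.subset(loci=keep)
    else:
        warnings.warn("no amplicon map; per-amplicon thinning skipped")

    r = rbar_d_matrix(gm)
    active = {lid: i for i, lid in enumerate(gm.locus_ids)}
    while True:
        best_pair = None
        best_val = max_rbar_d
        for la, i in active.items():
            for lb, j in active.items():
                if i < j and not np.isnan(r[i, j]) and r[i, j] > best_val:
                    best_val = r[i, j]
                    best_pair = (la, lb)
        if best_pair is None:
            break
        la, lb = best_pair
        drop = min(la, lb, key=rank)
        removed.append(
            {"id": drop, "kind": "locus", "reason": "linkage_thin", "stage": 7}
        )
        del active[drop]
    out = gm.subset(loci=[l for l in gm.locus_ids if l in active])
    return out, removed


# -- orchestration -----------------------------------------------------


def run_qc(
    gm: GenotypeMatrix,
    thresholds: QCThresholds | None = None,
    seed: int = 0,
) -> QCReport:
    """Apply the full QC procedure in its fixed stage order."""
    th = thresholds or QCThresholds()
    removed: list[dict] = []
    notes: list[str] = []

    cur, rem = filter_loci(gm, th.min_locus_call_rate, th.max_abs_fis)
    removed += rem
    cur, rem = filter_samples(cur, th.min_sample_call_rate, th.max_contamination)
    removed += rem

    groups, kept = find_duplicates(cur, th.dup_identity, seed=seed)
    drop = []
    for g in groups:
        keep_member = next(m for m in g if m in kept)
        for m in g:
            if m != keep_member:
                drop.append(m)
                removed.append(
                    {"id": m, "kind": "sample", "reason": "duplicate", "stage": 5}
                )
    if drop:
        cur = cur.subset(samples=[s for s in cur.sample_ids if s not in set(drop)])
    notes.append(f"{len(groups)} duplicate groups")

    cur, rem = thin_linkage(cur, th.max_rbar_d)
    removed += rem

    return QCReport(thresholds=th, seed=seed, retained=cur, removed=removed,
                    notes=notes)
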