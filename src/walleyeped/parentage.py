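"""Cohort assignment and likelihood-based parent-offspring assignment.

Juveniles are assigned to annual cohorts by total length (age-0 at <= 190 mm
TL; age-1 at 190-275 mm TL, belonging to the previous year's cohort; longer
fish are excluded). Offspring are then assigned to candidate parents with a
per-offspring Bayesian posterior over each sex's candidate set plus an
explicit "unsampled parent" class, built from multilocus likelihood ratios
under a Mendelian transmission model with a genotyping-error model in which
an observed call equals the true genotype with probability 1 - e and is
otherwise an independent Hardy-Weinberg draw.

This is a deliberate simplification of full-pedigree maximum-likelihood
sibship engines: each offspring is assigned independently, and unsampled
mates are recovered afterwards by clustering half-/full-sib likelihood
ratios among offspring that share one assigned parent. The accept/reject
semantics (assignment accepted when its posterior probability exceeds 0.90)
are preserved.

Per-locus parental likelihood, for candidate observed call ``po`` and
offspring observed call ``oo``::

    L_par(oo | po) = sum_t P(t | po) sum_g T(g | t, p) P(oo | g)

where P(t | po) is the Bayes posterior of the candidate's true genotype
under HWE, T(g | t, p) the transmission distribution (one allele from the
parent, the other from the allele frequency p), and P(oo | g) the error
model. The background likelihood is the HWE probability of the offspring
call, which is invariant under this error model. Missing calls contribute a
likelihood ratio of 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import logsumexp

from .genotypes import GenotypeMatrix

__all__ = [
    "CohortRule",
    "ParentageAssignment",
    "assign_cohort",
    "ParentageModel",
    "genotype_likelihood",
    "assign_parentage",
    "assign_all",
    "fullsib_partition",
    "infer_unsampled_mates",
    "count_mates",
    "parent_overlap_check",
]

MISS = 3  # integer code for a missing call


@dataclass(frozen=True)
class CohortRule:
    """Length cutoffs delineating juvenile ages at fall capture."""

    age0_max_tl: float = 190.0
    age1_max_tl: float = 275.0

    def __post_init__(self) -> None:
        if not self.age0_max_tl < self.age1_max_tl:
            raise ValueError("age0 cutoff must be below age1 cutoff")


def assign_cohort(
    tl: float, capture_year: int, rule: CohortRule = CohortRule()
) -> tuple[str, int | None]:
    """Cohort label for a juvenile of the given total length.

    Returns ("age0", capture_year), ("age1", capture_year - 1), or
    ("excluded", None).
    """
    if tl <= 0:
        raise ValueError(f"non-positive total length {tl}")
    if tl <= rule.age0_max_tl:
        return "age0", capture_year
    if tl <= rule.age1_max_tl:
        return "age1", capture_year - 1
    return "excluded", None


@dataclass
class ParentageAssignment:
    offspring_id: str
    cohort_year: int
    stage: str
    mother_id: str | None
    father_id: str | None
    mother_prob: float
    father_prob: float
    pair_prob: float
    n_exclusions_mother: int
    n_exclusions_father: int


def _encode(calls: np.ndarray) -> np.ndarray:
    """Float dosage with NaN -> int codes 0/1/2 and 3 for missing."""
    out = np.where(np.isnan(calls), MISS, calls).astype(np.int64)
    return out


class ParentageModel:
    """Precomputed per-locus log-likelihood tables for fast assignment."""

    def __init__(self, allele_freqs: np.ndarray, error_rate: float = 0.01):
        p = np.asarray(allele_freqs, dtype=float)
        self.ok = (p > 0) & (p < 1)
        if not self.ok.all():
            warnings.warn(
                f"{(~self.ok).sum()} loci with allele frequency outside (0,1) skipped"
            )
        self.p = p
        self.error_rate = float(error_rate)
        L = p.size
        e = self.error_rate
        g = np.arange(3.0)
        hwe = np.stack(
            [(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=1
        )  # (L, 3)
        # error model: P(obs o | true t) = (1-e) 1[o==t] + e * HWE(o)
        err = (1 - e) * np.eye(3)[None, :, :] + e * hwe[:, None, :]  # (L, t, o)
        # candidate true-genotype posterior given its observed call
        post = hwe[:, :, None] * err  # (L, t, o) ~ P(t) P(o|t)
        post = post / post.sum(axis=1, keepdims=True)  # P(t | o), axis t
        # transmission: parent true t -> offspring true g with other allele ~ p
        tau = g / 2.0
        trans = np.empty((L, 3, 3))  # (L, t, g)
        for ti, t in enumerate(tau):
            trans[:, ti, 0] = (1 - t) * (1 - p)
            trans[:, ti, 1] = t * (1 - p) + (1 - t) * p
            trans[:, ti, 2] = t * p
        # parental obs distribution: (L, parent obs, offspring obs)
        par = np.einsum("lto,ltg,lgq->loq", post, trans, err)
        bg = hwe  # background offspring obs distribution (L, 3)
        with np.errstate(divide="ignore"):
            T = np.log(par) - np.log(bg)[:, None, :]  # (L, po, oo)
        # pad with missing code: LR contribution 0
        self.loglr = np.zeros((L, 4, 4))
        self.loglr[:, :3, :3] = T
        self.loglr[~self.ok] = 0.0
        # Mendelian trio transmission tables for pair scoring
        mend = np.zeros((3, 3, 3))  # (mt, ft, g)
        for mt in range(3):
            for ft in range(3):
                pm, pf = mt / 2.0, ft / 2.0
                mend[mt, ft, 0] = (1 - pm) * (1 - pf)
                mend[mt, ft, 1] = pm * (1 - pf) + (1 - pm) * pf
                mend[mt, ft, 2] = pm * pf
        trio = np.einsum("ltm,lsf,tsg,lgq->lmfq", post, post, mend, err)
        with np.errstate(divide="ignore"):
            TT = np.log(trio) - np.log(bg)[:, None, None, :]
        self.trio_loglr = np.zeros((L, 4, 4, 4))
        self.trio_loglr[:, :3, :3, :3] = TT
        self.trio_loglr[~self.ok] = 0.0
        self._hwe = hwe
        self._err = err
        self._post = post
        self._trans = trans
        self._mend = mend
        self._larange = np.arange(L)

    # -- building blocks ----------------------------------------------

    def loglr_parent(self, off: np.ndarray, cands: np.ndarray) -> np.ndarray:
        """Multilocus log likelihood ratio (parental vs background) for each
        candidate row against one offspring. ``off``: (L,) codes;
        ``cands``: (n, L) codes."""
        return self.loglr[self._larange[None, :], cands, off[None, :]].sum(axis=1)

    def loglr_pair(
        self, off: np.ndarray, mom: np.ndarray, dad: np.ndarray
    ) -> float:
        return float(self.trio_loglr[self._larange, mom, dad, off].sum())

    def n_exclusions(self, off: np.ndarray, cand: np.ndarray) -> int:
        """Opposing-homozygote locus count (0 vs 2)."""
        return int(
            np.sum(((off == 0) & (cand == 2)) | ((off == 2) & (cand == 0)))
        )


def genotype_likelihood(
    offspring_call: float,
    parent_call: float,
    p_hat: float,
    error_rate: float = 0.01,
) -> tuple[float, float]:
    """Per-locus (parental likelihood, background likelihood) for a single
    observed offspring/candidate call pair. Missing calls give (1, 1)."""
    if not 0 < p_hat < 1:
        warnings.warn(f"allele frequency {p_hat} outside (0,1); locus skipped")
        return 1.0, 1.0
    model = ParentageModel(np.array([p_hat]), error_rate)
    oc = MISS if np.isnan(offspring_call) else int(offspring_call)
    pc = MISS if np.isnan(parent_call) else int(parent_call)
    if oc == MISS or pc == MISS:
        return 1.0, 1.0
    hwe = model._hwe[0]
    par = np.einsum("to,tg,gq->oq", model._post[0], model._trans[0], model._err[0])
    return float(par[pc, oc]), float(hwe[oc])


def _posterior(loglrs: np.ndarray) -> np.ndarray:
    """Posterior over candidates + the unsampled class (last entry), with a
    uniform prior of 1/(n+1) on each class."""
    full = np.append(loglrs, 0.0)  # unsampled: LR = 1
    return np.exp(full - logsumexp(full))


def assign_parentage(
    offspring_id: str,
    off_calls: np.ndarray,
    candidates_by_sex: dict[str, tuple[list[str], np.ndarray]],
    model: ParentageModel,
    accept_prob: float = 0.90,
    cohort_year: int = 0,
    stage: str = "age0",
) -> ParentageAssignment:
    """Assign one offspring to a mother and father (or the unsampled class).

    ``candidates_by_sex`` maps "F"/"M" to (ids, coded call matrix); fish of
    unknown sex appear in both sets. The best candidate per sex is accepted
    when its posterior exceeds ``accept_prob``; an accepted mother/father
    pair is additionally scored as a trio against the one-parent and
    no-parent alternatives, and a single fish is never kept on both sides.
    """
    off = _encode(off_calls) if off_calls.dtype != np.int64 else off_calls
    best: dict[str, tuple[str | None, float, np.ndarray | None]] = {}
    for s in ("F", "M"):
        ids, calls = candidates_by_sex.get(s, ([], np.empty((0, off.size), int)))
        usable = [i for i, cid in enumerate(ids) if cid != offspring_id]
        if not usable:
            best[s] = (None, 0.0, None)
            continue
        calls = calls[usable]
        ids = [ids[i] for i in usable]
        lrs = model.loglr_parent(off, calls)
        post = _posterior(lrs)
        k = int(np.argmax(post[:-1]))
        best[s] = (ids[k], float(post[k]), calls[k])

    mom_id, mom_p, mom_calls = best["F"]
    dad_id, dad_p, dad_calls = best["M"]
    # unknown-sex fish may top both lists; the higher posterior wins
    if mom_id is not None and mom_id == dad_id:
        if mom_p >= dad_p:
            dad_id, dad_p, dad_calls = None, 0.0, None
        else:
            mom_id, mom_p, mom_calls = None, 0.0, None

    mom_ok = mom_id is not None and mom_p > accept_prob
    dad_ok = dad_id is not None and dad_p > accept_prob
    pair_prob = 0.0
    if mom_ok and dad_ok:
        l_pair = model.loglr_pair(off, mom_calls, dad_calls)
        l_m = float(model.loglr_parent(off, mom_calls[None, :])[0])
        l_f = float(model.loglr_parent(off, dad_calls[None, :])[0])
        arr = np.array([l_pair, l_m, l_f, 0.0])
        pair_prob = float(np.exp(arr[0] - logsumexp(arr)))

    n_em = model.n_exclusions(off, mom_calls) if mom_ok else 0
    n_ef = model.n_exclusions(off, dad_calls) if dad_ok else 0
    return ParentageAssignment(
        offspring_id=offspring_id,
        cohort_year=cohort_year,
        stage=stage,
        mother_id=mom_id if mom_ok else None,
        father_id=dad_id if dad_ok else None,
        mother_prob=mom_p,
        father_prob=dad_p,
        pair_prob=pair_prob,
        n_exclusions_mother=n_em,
        n_exclusions_father=n_ef,
    )


def assign_all(
    gm: GenotypeMatrix,
    metadata: pd.DataFrame,
    allele_freqs: np.ndarray | None = None,
    error_rate: float = 0.01,
    accept_prob: float = 0.90,
    rule: CohortRule = CohortRule(),
) -> pd.DataFrame:
    """Run parentage for every genotyped juvenile, one analysis per
    collection year with all candidate parents included regardless of the
    year they were sampled.

    Allele frequencies default to the QC'd panel's observed frequencies.
    Returns a pedigree DataFrame (one row per juvenile).
    """
    if allele_freqs is None:
        called = ~np.isnan(gm.calls)
        allele_freqs = np.nansum(gm.calls, axis=0) / (
            2 * np.maximum(called.sum(axis=0), 1)
        )
    model = ParentageModel(allele_freqs, error_rate)
    codes = _encode(gm.calls)
    idx = {s: i for i, s in enumerate(gm.sample_ids)}

    adults = metadata[metadata.stage == "adult"]
    sex_of: dict[str, str] = {}
    for fid, grp in adults.groupby("fish_id"):
        sexes = set(grp.sex) - {"U"}
        sex_of[fid] = sexes.pop() if len(sexes) == 1 else "U"
    adult_ids = [f for f in sex_of if f in idx]
    female_ids = [f for f in adult_ids if sex_of[f] in ("F", "U")]
    male_ids = [f for f in adult_ids if sex_of[f] in ("M", "U")]
    cands = {
        "F": (female_ids, codes[[idx[f] for f in female_ids]]),
        "M": (male_ids, codes[[idx[f] for f in male_ids]]),
    }

    rows = []
    juv = metadata[metadata.stage.isin(["age0", "age1"])]
    for _, r in juv.iterrows():
        if r.fish_id not in idx:
            continue
        label, cohort = assign_cohort(r.length_mm, int(r.year), rule)
        if label == "excluded":
            continue
        a = assign_parentage(
            r.fish_id,
            codes[idx[r.fish_id]],
            cands,
            model,
            accept_prob=accept_prob,
            cohort_year=int(cohort),
            stage=label,
        )
        rows.append(
            {
                "offspring_id": a.offspring_id,
                "cohort_year": a.cohort_year,
                "stage": a.stage,
                "mother_id": a.mother_id,
                "mother_prob": round(a.mother_prob, 6),
                "father_id": a.father_id,
                "father_prob": round(a.father_prob, 6),
                "pair_prob": round(a.pair_prob, 6),
                "n_excl_m": a.n_exclusions_mother,
                "n_excl_f": a.n_exclusions_father,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "offspring_id", "cohort_year", "stage", "mother_id", "mother_prob",
            "father_id", "father_prob", "pair_prob", "n_excl_m", "n_excl_f",
        ],
    )


# -- unsampled-mate inference ------------------------------------------


def fullsib_partition(
    offspring_ids: list[str],
    off_codes: np.ndarray,
    shared_parent_codes: np.ndarray,
    model: ParentageModel,
) -> list[list[str]]:
    """Cluster offspring sharing one assigned parent into full-sib groups,
    each group representing one unsampled co-parent.

    Pairwise full-sib vs half-sib log likelihood ratio given the shared
    parent; clusters are connected components of the LR > 1 graph (greedy
    single linkage). A single offspring forms its own cluster.
    """
    n = len(offspring_ids)
    if n == 1:
        return [list(offspring_ids)]
    p = model.p
    post_sp = model._post[np.arange(p.size), :, np.minimum(shared_parent_codes, 2)]
    post_sp = np.where(
        (shared_parent_codes == MISS)[:, None], model._hwe, post_sp
    )  # (L, t)
    # P(obs o | shared-parent true t, mate ~ HWE): transmission then error
    p_obs_t = np.einsum("ltg,lgq->ltq", model._trans, model._err)  # (L, t, q)
    # P(obs o | t, mate true u)
    p_obs_tu = np.einsum("tug,lgq->ltuq", model._mend, model._err)  # (L,t,u,q)
    hwe = model._hwe
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            oi, oj = off_codes[i], off_codes[j]
            ok = (oi != MISS) & (oj != MISS) & model.ok
            if not ok.any():
                continue
            l = np.flatnonzero(ok)
            l_hs = np.einsum(
                "lt,lt,lt->l",
                post_sp[l],
                p_obs_t[l, :, oi[l]].reshape(len(l), 3),
                p_obs_t[l, :, oj[l]].reshape(len(l), 3),
            )
            pi = p_obs_tu[l][:, :, :, :]
            a = pi[np.arange(len(l)), :, :, oi[l]]  # (l, t, u)
            b = pi[np.arange(len(l)), :, :, oj[l]]
            l_fs = np.einsum("lt,lu,ltu,ltu->l", post_sp[l], hwe[l], a, b)
            with np.errstate(divide="ignore"):
                loglr = np.log(l_fs) - np.log(l_hs)
            adj[i, j] = adj[j, i] = loglr.sum() > 0.0
    _, labels = connected_components(csr_matrix(adj), directed=False)
    groups: dict[int, list[str]] = {}
    for k, lab in enumerate(labels):
        groups.setdefault(lab, []).append(offspring_ids[k])
    return list(groups.values())


def infer_unsampled_mates(
    assignments: pd.DataFrame,
    gm: GenotypeMatrix,
    allele_freqs: np.ndarray | None = None,
    error_rate: float = 0.01,
) -> pd.DataFrame:
    """Fill unassigned parent slots with inferred unsampled-mate cluster ids.

    Offspring of one assigned parent are partitioned into full-sib clusters;
    each cluster receives a distinct id ``<parent>:<year>:U<k>`` standing in
    for one unsampled mate. Only the mate-count summaries use these ids.
    """
    if allele_freqs is None:
        called = ~np.isnan(gm.calls)
        allele_freqs = np.nansum(gm.calls, axis=0) / (
            2 * np.maximum(called.sum(axis=0), 1)
        )
    model = ParentageModel(allele_freqs, error_rate)
    codes = _encode(gm.calls)
    idx = {s: i for i, s in enumerate(gm.sample_ids)}
    out = assignments.copy()
    for (year,), sub in assignments.groupby(["cohort_year"]):
        for parent_col, other_col in (
            ("mother_id", "father_id"),
            ("father_id", "mother_id"),
        ):
            hit = sub[sub[parent_col].notna() & sub[other_col].isna()]
            for pid, grp in hit.groupby(parent_col):
                oids = list(grp.offspring_id)
                clusters = fullsib_partition(
                    oids,
                    np.stack([codes[idx[o]] for o in oids]),
                    codes[idx[pid]] if pid in idx else np.full(len(model.p), MISS),
                    model,
                )
                for k, members in enumerate(clusters):
                    cid = f"{pid}:{year}:U{k}"
                    out.loc[
                        out.offspring_id.isin(members)
                        & (out.cohort_year == year),
                        other_col,
                    ] = cid
    return out


def count_mates(assignments: pd.DataFrame, year: int) -> pd.DataFrame:
    """Distinct co-parents (sampled or inferred unsampled) per parent.

    Expects assignments where unassigned sides have been filled by
    :func:`infer_unsampled_mates`; run on raw assignments, offspring with no
    co-parent id are skipped for that parent.
    """
    sub = assignments[assignments.cohort_year == year]
    rows = []
    for col, other, role in (
        ("mother_id", "father_id", "mother"),
        ("father_id", "mother_id", "father"),
    ):
        real = sub[sub[col].notna() & ~sub[col].astype(str).str.contains(":U")]
        for pid, grp in real.groupby(col):
            mates = grp[other].dropna().unique()
            rows.append(
                {
                    "parent_id": pid,
                    "year": year,
                    "role": role,
                    "n_mates": max(len(mates), 1),
                }
            )
    return pd.DataFrame(rows, columns=["parent_id", "year", "role", "n_mates"])


def parent_overlap_check(
    parents_age0_year_t: set[str], parents_age1_year_t1: set[str]
) -> dict[str, float]:
    """Overlap between parents of a cohort detected via age-0 fish and the
    same cohort's parents detected via age-1 fish the following year.

    Reports both denominators (the union, and the age-0 parent count) since
    either convention is defensible.
    """
    a, b = set(parents_age0_year_t), set(parents_age1_year_t1)
    union = a | b
    if not union:
        warnings.warn("empty parent union; overlap undefined")
        return {"jaccard": np.nan, "frac_of_age0": np.nan, "n_shared": 0}
    shared = a & b
    return {
        "jaccard": len(shared) / len(union),
        "frac_of_age0": len(shared) / len(a) if a else np.nan,
        "n_shared": len(shared),
    }
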