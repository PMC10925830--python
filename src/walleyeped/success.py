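"""Mortality-corrected logistic models of reproductive success.

Builds a fish x year success table from the survey metadata and accepted
parentage assignments (success = at least one accepted age-0 assignment that
year; only age-3+ rows, sexes known directly or via parentage), applies the
known-alive rule (a fish is alive in a year if it was sampled or identified
as a parent in that year or any later year), and corrects for unknown fates
by Monte-Carlo mortality imputation: from the year after a fish's last
known-alive year onward, annual survival is drawn Bernoulli(1 - 0.198)
sequentially and dead fish-years are excluded from that iteration.

Sex-specific univariate logistic models (total length, age, growth-rate
percentile) and an eight-model BIC selection procedure are each run over
many imputation iterations; per-model medians of coefficients, standard
errors, Wald p values, Nagelkerke R^2, odds ratios and confidence bounds are
reported, together with the per-iteration lowest-BIC tally and the selected
model's median BIC weight and delta-BIC. Median-of-iterations p values
follow the source convention for this analysis; they are a summary of the
iteration distribution, not a combined test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "ModelFit",
    "IterationSummary",
    "growth_percentile",
    "build_success_table",
    "known_alive",
    "mortality_impute",
    "fit_logistic",
    "predict_probability",
    "odds_ratio_ci",
    "run_univariate",
    "CANDIDATE_MODELS",
    "select_model",
]

Z95 = 1.96

CANDIDATE_MODELS: dict[int, tuple[str, ...]] = {
    1: (),
    2: ("age",),
    3: ("year",),
    4: ("growth",),
    5: ("age", "growth"),
    6: ("age", "year"),
    7: ("growth", "year"),
    8: ("growth", "age", "year"),
}


# -- table construction ------------------------------------------------


def growth_percentile(
    tl: float, age: int, sex: str, reference: pd.DataFrame
) -> float:
    """Midrank percentile of ``tl`` within the sex- and age-specific
    reference length distribution: (n_less + 0.5 n_equal) / n.

    A fish above every reference length scores 1.0 (less if tied). Returns
    NaN when the reference for (sex, age) is empty.
    """
    ref = reference[(reference.sex == sex) & (reference.age == age)]["length_mm"]
    ref = ref.dropna().to_numpy()
    if ref.size == 0:
        return np.nan
    return float(((ref < tl).sum() + 0.5 * (ref == tl).sum()) / ref.size)


def known_alive(
    fish_id: str, year: int, encounter_years: dict[str, set[int]]
) -> bool:
    """True when the fish was sampled or assigned as a parent in ``year`` or
    any later year (a later encounter implies it was alive earlier)."""
    ys = encounter_years.get(fish_id, set())
    return bool(ys) and year <= max(ys)


def _encounters(
    metadata: pd.DataFrame, assignments: pd.DataFrame
) -> dict[str, set[int]]:
    enc: dict[str, set[int]] = {}
    for _, r in metadata[metadata.stage == "adult"].iterrows():
        enc.setdefault(r.fish_id, set()).add(int(r.year))
    for col in ("mother_id", "father_id"):
        sub = assignments[assignments[col].notna()]
        sub = sub[~sub[col].astype(str).str.contains(":U")]
        for pid, years in sub.groupby(col)["cohort_year"]:
            enc.setdefault(pid, set()).update(int(y) for y in years)
    return enc


def build_success_table(
    metadata: pd.DataFrame,
    assignments: pd.DataFrame,
    years: list[int] | None = None,
    min_age: int = 3,
    reference: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fish x year table of reproductive-success outcomes and covariates.

    One row per adult per study year in which the fish is at least
    ``min_age``. Sex comes from the survey record, or from the parentage
    role when the survey recorded it as unknown. Growth percentile is
    assigned once from the fish's first ageing (midrank within the sex/age
    reference distribution, by default the adult survey records themselves)
    and treated as constant over time. ``tl_measured`` is present only in
    years the fish was handled.
    """
    adults = metadata[metadata.stage == "adult"].copy()
    if years is None:
        years = sorted(
            set(metadata.year.astype(int)) | set(assignments.cohort_year.astype(int))
        )
    if reference is None:
        reference = adults[adults.sex.isin(["F", "M"])]

    mothers = set(assignments.mother_id.dropna().astype(str))
    fathers = set(assignments.father_id.dropna().astype(str))
    mothers = {m for m in mothers if ":U" not in m}
    fathers = {f for f in fathers if ":U" not in f}

    succ_by_year: dict[int, set[str]] = {}
    age0 = assignments[assignments.stage == "age0"]
    for y, grp in age0.groupby("cohort_year"):
        ids = set(grp.mother_id.dropna().astype(str)) | set(
            grp.father_id.dropna().astype(str)
        )
        succ_by_year[int(y)] = {i for i in ids if ":U" not in i}

    enc = _encounters(metadata, assignments)

    rows = []
    for fid, grp in adults.groupby("fish_id"):
        grp = grp.sort_values("year")
        sexes = set(grp.sex) - {"U"}
        if len(sexes) == 1:
            sex = sexes.pop()
        elif fid in mothers and fid not in fathers:
            sex = "F"
        elif fid in fathers and fid not in mothers:
            sex = "M"
        else:
            sex = "U"
        first = grp.iloc[0]
        base_year, base_age = int(first.year), first.age
        if pd.isna(base_age):
            continue
        gp = (
            growth_percentile(first.length_mm, int(base_age), sex, reference)
            if sex in ("F", "M") and pd.notna(first.length_mm)
            else np.nan
        )
        handled = {int(r.year): r.length_mm for _, r in grp.iterrows()}
        last_known = max(enc.get(fid, {base_year}))
        for y in years:
            age_in_year = int(base_age) + (y - base_year)
            if age_in_year < min_age:
                continue
            rows.append(
                {
                    "fish_id": fid,
                    "sex": sex,
                    "year": y,
                    "success": int(fid in succ_by_year.get(y, set())),
                    "age_in_year": age_in_year,
                    "growth_percentile": gp,
                    "tl_measured": handled.get(y, np.nan),
                    "known_alive": y <= last_known,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "fish_id", "sex", "year", "success", "age_in_year",
            "growth_percentile", "tl_measured", "known_alive",
        ],
    )


def mortality_impute(
    table: pd.DataFrame, rate: float = 0.198, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Inclusion flags for one imputation iteration.

    Known-alive fish-years are always included. For each fish, starting the
    year after its last known-alive year, annual survival is drawn
    Bernoulli(1 - rate) sequentially; once dead the fish is excluded for
    that year and all later years.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"mortality rate {rate} outside [0,1]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    included = np.zeros(len(table), dtype=bool)
    order = np.lexsort((table.year.to_numpy(), table.fish_id.to_numpy()))
    ka = table.known_alive.to_numpy()
    fid = table.fish_id.to_numpy()
    prev_fish = None
    alive = True
    for i in order:
        if fid[i] != prev_fish:
            prev_fish = fid[i]
            alive = True
        if ka[i]:
            included[i] = True
            alive = True  # known alive resets the chain
        else:
            if alive:
                alive = rng.random() < (1 - rate)
            included[i] = alive
    return included


# -- model fitting -----------------------------------------------------


@dataclass
class ModelFit:
    model_id: int
    terms: tuple[str, ...]
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    wald_p: np.ndarray
    nagelkerke_r2: float
    bic: float
    loglik: float
    n: int
    ok: bool = True
    flags: list[str] = field(default_factory=list)

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    def or_ci(self, z: float = Z95) -> tuple[np.ndarray, np.ndarray]:
        return np.exp(self.coef - z * self.se), np.exp(self.coef + z * self.se)


def odds_ratio_ci(coef: float, se: float, z: float = Z95) -> tuple[float, float, float]:
    """Odds ratio and Wald 95 % CI bounds for one coefficient."""
    return float(np.exp(coef)), float(np.exp(coef - z * se)), float(np.exp(coef + z * se))


def fit_logistic(
    y: np.ndarray,
    design: np.ndarray,
    names: list[str] | None = None,
    model_id: int = 0,
    terms: tuple[str, ...] = (),
) -> ModelFit:
    """Maximum-likelihood logistic fit with Wald inference.

    ``design`` must include the intercept column. Nagelkerke R^2 rescales
    the Cox-Snell likelihood ratio; BIC = -2 logL + k ln n. Complete
    separation or a zero-variance covariate flags the fit as not ok.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    n, k = X.shape
    names = names or [f"b{i}" for i in range(k)]
    flags: list[str] = []
    if y.sum() == 0 or y.sum() == n:
        return ModelFit(model_id, terms, names, np.full(k, np.nan),
                        np.full(k, np.nan), np.full(k, np.nan), np.nan, np.nan,
                        np.nan, n, ok=False, flags=["all-one-class"])
    if k > 1 and np.any(X[:, 1:].std(axis=0) < 1e-12):
        return ModelFit(model_id, terms, names, np.full(k, np.nan),
                        np.full(k, np.nan), np.full(k, np.nan), np.nan, np.nan,
                        np.nan, n, ok=False, flags=["zero-variance covariate"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                maxiter=100, tol=1e-8
            )
        except Exception as exc:  # pragma: no cover - rare numeric failures
            return ModelFit(model_id, terms, names, np.full(k, np.nan),
                            np.full(k, np.nan), np.full(k, np.nan), np.nan,
                            np.nan, np.nan, n, ok=False, flags=[str(exc)])
    coef = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)
    if np.any(np.abs(coef) > 30) or np.any(se > 1e3) or not np.all(np.isfinite(se)):
        flags.append("separation")
    ll1 = float(res.llf)
    pbar = y.mean()
    ll0 = float(y.sum() * np.log(pbar) + (n - y.sum()) * np.log(1 - pbar))
    cox_snell = 1 - np.exp(2 / n * (ll0 - ll1))
    r2 = float(cox_snell / (1 - np.exp(2 / n * ll0)))
    bic = -2 * ll1 + k * np.log(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald_p = 2 * norm.sf(np.abs(coef / se))
    return ModelFit(
        model_id=model_id,
        terms=terms,
        names=names,
        coef=coef,
        se=se,
        wald_p=wald_p,
        nagelkerke_r2=r2,
        bic=float(bic),
        loglik=ll1,
        n=n,
        ok="separation" not in flags,
        flags=flags,
    )


def predict_probability(coef: np.ndarray, covariates: np.ndarray) -> float:
    """Inverse-logit of the linear predictor (intercept first)."""
    x = np.concatenate([[1.0], np.atleast_1d(np.asarray(covariates, dtype=float))])
    return float(expit(np.dot(np.asarray(coef, dtype=float), x)))


# -- design matrices ---------------------------------------------------

TRAIT_COLUMN = {"tl": "tl_measured", "age": "age_in_year", "growth": "growth_percentile"}


def _design(rows: pd.DataFrame, terms: tuple[str, ...], years: list[int]):
    cols = [np.ones(len(rows))]
    names = ["intercept"]
    for t in terms:
        if t == "year":
            for y in years[1:]:
                cols.append((rows.year == y).to_numpy(float))
                names.append(f"year_{y}")
        else:
            cols.append(rows[TRAIT_COLUMN[t]].to_numpy(float))
            names.append(t)
    return np.column_stack(cols), names


def _iteration_rows(
    table: pd.DataFrame,
    sex: str,
    terms: tuple[str, ...],
    rate: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    included = mortality_impute(table, rate, rng)
    rows = table[included & (table.sex == sex)]
    for t in terms:
        if t != "year":
            rows = rows[rows[TRAIT_COLUMN[t]].notna()]
    return rows


@dataclass
class IterationSummary:
    """Median-of-iterations model statistics (and the selection tally)."""

    label: str
    sex: str
    n_iter: int
    master_seed: int
    medians: pd.DataFrame  # per-coefficient medians: coef, se, p, or, ci
    median_r2: float
    median_bic: float
    median_n: float
    n_failed: int
    tally: dict[int, int] | None = None
    selected_model: int | None = None
    median_bic_weight: float | None = None
    median_delta_bic: float | None = None


def _aggregate(
    fits: list[ModelFit], label: str, sex: str, n_iter: int, master_seed: int
) -> IterationSummary:
    ok = [f for f in fits if f.ok]
    n_failed = len(fits) - len(ok)
    if n_failed > 0.5 * len(fits):
        raise RuntimeError(
            f"{n_failed}/{len(fits)} iterations failed to fit for {label}/{sex}"
        )
    names = ok[0].names
    coef = np.median([f.coef for f in ok], axis=0)
    se = np.median([f.se for f in ok], axis=0)
    p = np.median([f.wald_p for f in ok], axis=0)
    or_ = np.median([f.odds_ratios for f in ok], axis=0)
    lo = np.median([f.or_ci()[0] for f in ok], axis=0)
    hi = np.median([f.or_ci()[1] for f in ok], axis=0)
    med = pd.DataFrame(
        {"coef": coef, "se": se, "wald_p": p, "odds_ratio": or_,
         "or_lo95": lo, "or_hi95": hi},
        index=names,
    )
    return IterationSummary(
        label=label,
        sex=sex,
        n_iter=n_iter,
        master_seed=master_seed,
        medians=med,
        median_r2=float(np.median([f.nagelkerke_r2 for f in ok])),
        median_bic=float(np.median([f.bic for f in ok])),
        median_n=float(np.median([f.n for f in ok])),
        n_failed=n_failed,
    )


def run_univariate(
    table: pd.DataFrame,
    trait: str,
    sex: str,
    n_iter: int = 1000,
    rate: float = 0.198,
    master_seed: int = 0,
) -> IterationSummary:
    """Sex-specific univariate logistic model of success on one trait,
    medianized over mortality-imputation iterations.

    ``trait`` is one of "tl", "age", "growth". Total length rows are limited
    to fish-years where the fish was handled and measured.
    """
    if trait not in TRAIT_COLUMN:
        raise ValueError(f"unknown trait {trait!r}")
    years = sorted(table.year.unique())
    ss = np.random.SeedSequence(master_seed)
    fits = []
    for child in ss.spawn(n_iter):
        rng = np.random.default_rng(child)
        rows = _iteration_rows(table, sex, (trait,), rate, rng)
        X, names = _design(rows, (trait,), years)
        fits.append(fit_logistic(rows.success.to_numpy(), X, names, terms=(trait,)))
    return _aggregate(fits, f"univariate:{trait}", sex, n_iter, master_seed)


def select_model(
    table: pd.DataFrame,
    sex: str,
    n_iter: int = 1000,
    rate: float = 0.198,
    master_seed: int = 0,
) -> IterationSummary:
    """Two-step BIC model selection over the eight candidate models.

    Pass 1 tallies, per imputation iteration, which candidate has the lowest
    BIC (ties go to the lower model id and are logged); the winner is the
    most-tallied model. Pass 2 reruns fresh iterations fitting the winner to
    medianize its coefficients, its BIC weight
    (exp(-dBIC/2) / sum over candidates) and its delta-BIC to the runner-up.
    Total length is not a candidate covariate (it cannot be carried across
    years); year enters as a categorical factor.
    """
    years = sorted(table.year.unique())
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(2 * n_iter)
    tally = {m: 0 for m in CANDIDATE_MODELS}
    ties = 0
    for child in children[:n_iter]:
        rng = np.random.default_rng(child)
        rows = _iteration_rows(table, sex, ("age", "growth"), rate, rng)
        bics = {}
        for mid, terms in CANDIDATE_MODELS.items():
            X, names = _design(rows, terms, years)
            f = fit_logistic(rows.success.to_numpy(), X, names, mid, terms)
            if f.ok:
                bics[mid] = f.bic
        if not bics:
            continue
        lo = min(bics.values())
        winners = [m for m, b in bics.items() if b <= lo + 1e-9]
        if len(winners) > 1:
            ties += 1
        tally[min(winners)] += 1

    selected = max(tally, key=lambda m: (tally[m], -m))
    terms = CANDIDATE_MODELS[selected]
    fits = []
    weights = []
    deltas = []
    for child in children[n_iter:]:
        rng = np.random.default_rng(child)
        rows = _iteration_rows(table, sex, ("age", "growth"), rate, rng)
        bics = {}
        keep = None
        for mid, mterms in CANDIDATE_MODELS.items():
            X, names = _design(rows, mterms, years)
            f = fit_logistic(rows.success.to_numpy(), X, names, mid, mterms)
            if f.ok:
                bics[mid] = f.bic
            if mid == selected:
                keep = f
        if keep is None or not keep.ok or selected not in bics:
            fits.append(keep if keep is not None else
                        ModelFit(selected, terms, ["intercept"], np.array([np.nan]),
                                 np.array([np.nan]), np.array([np.nan]), np.nan,
                                 np.nan, np.nan, 0, ok=False))
            continue
        fits.append(keep)
        rel = np.array(list(bics.values())) - min(bics.values())
        w = np.exp(-rel / 2)
        w /= w.sum()
        weights.append(float(w[list(bics).index(selected)]))
        others = [b for m, b in bics.items() if m != selected]
        deltas.append(float(min(others) - bics[selected]) if others else np.nan)

    out = _aggregate(fits, f"selection:model{selected}", sex, n_iter, master_seed)
    out.tally = tally
    out.selected_model = selected
    out.median_bic_weight = float(np.median(weights)) if weights else np.nan
    out.median_delta_bic = float(np.median(deltas)) if deltas else np.nan
    if ties:
        out.medians.attrs["bic_ties"] = ties
    return out
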