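"""Pipeline orchestration and summary tables.

Produces the study's summary surfaces from the pipeline outputs: per-year
assignment-rate tables, mate-count tables, parent-overlap (Venn) counts
across years, and a provenance record; ``run_all`` chains
simulate -> QC -> parentage -> accumulation -> success models end to end.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import accumulation as acc
from . import parentage as par
from . import qc as qcmod
from . import success as suc
from . import synthetic as syn
from .genotypes import GenotypeMatrix, read_genotype_csv, read_metadata

log = logging.getLogger("walleyeped")

__all__ = [
    "RunConfig",
    "summarize_assignments",
    "summarize_mates",
    "summarize_overlap",
    "run_all",
]


def summarize_assignments(
    assignments: pd.DataFrame,
) -> pd.DataFrame:
    """Per year x stage assignment rates.

    ``one_parent`` counts offspring with at least one assigned parent
    (the convention used in study-style summary tables); ``exactly_one``
    is the exclusive category; zero/exactly-one/both partition the cohort.
    """
    rows = []
    for (stage, year), grp in assignments.groupby(["stage", "cohort_year"]):
        n = len(grp)
        has_m = grp.mother_id.notna()
        has_f = grp.father_id.notna()
        both = int((has_m & has_f).sum())
        one_plus = int((has_m | has_f).sum())
        rows.append(
            {
                "stage": stage,
                "year": int(year),
                "potential_offspring": n,
                "mother_n": int(has_m.sum()),
                "mother_pct": round(100 * has_m.mean(), 1) if n else 0.0,
                "father_n": int(has_f.sum()),
                "father_pct": round(100 * has_f.mean(), 1) if n else 0.0,
                "zero_parents_n": n - one_plus,
                "zero_parents_pct": round(100 * (n - one_plus) / n, 1) if n else 0.0,
                "one_parent_n": one_plus,
                "one_parent_pct": round(100 * one_plus / n, 1) if n else 0.0,
                "exactly_one_n": one_plus - both,
                "both_parents_n": both,
                "both_parents_pct": round(100 * both / n, 1) if n else 0.0,
            }
        )
    return pd.DataFrame(rows).sort_values(["stage", "year"]).reset_index(drop=True)


def summarize_mates(mate_counts: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of mates per parent for each role x year, plus a grand
    row per role (the mean of the yearly means)."""
    rows = []
    for (role, year), grp in mate_counts.groupby(["role", "year"]):
        rows.append(
            {
                "role": role,
                "year": int(year),
                "n_parents": len(grp),
                "mean_mates": float(grp.n_mates.mean()),
                "sd_mates": float(grp.n_mates.std(ddof=1)) if len(grp) > 1 else 0.0,
            }
        )
    out = pd.DataFrame(rows)
    for role, grp in out.groupby("role"):
        rows.append(
            {
                "role": role,
                "year": 0,  # grand row
                "n_parents": int(grp.n_parents.sum()),
                "mean_mates": float(grp.mean_mates.mean()),
                "sd_mates": float(grp.sd_mates.mean()),
            }
        )
    return pd.DataFrame(rows).reset_index(drop=True)


def summarize_overlap(assignments: pd.DataFrame, stage: str = "age0") -> dict[str, int]:
    """Venn cells: how many parents have detected offspring in each
    combination of cohort years. Keys are '+'-joined sorted years."""
    sub = assignments[assignments.stage == stage]
    years_of: dict[str, set[int]] = {}
    for col in ("mother_id", "father_id"):
        s = sub[sub[col].notna()]
        s = s[~s[col].astype(str).str.contains(":U")]
        for pid, ys in s.groupby(col)["cohort_year"]:
            years_of.setdefault(pid, set()).update(int(y) for y in ys)
    cells: dict[str, int] = {}
    for pid, ys in years_of.items():
        key = "+".join(str(y) for y in sorted(ys))
        cells[key] = cells.get(key, 0) + 1
    return dict(sorted(cells.items()))


@dataclass
class RunConfig:
    """End-to-end run configuration; every threshold and seed is echoed in
    the provenance record."""

    out_dir: str = "walleyeped_run"
    simulate: bool = True
    sim: syn.SimConfig = field(default_factory=syn.SimConfig)
    genotypes_path: str | None = None
    loci_path: str | None = None
    metadata_path: str | None = None
    qc: qcmod.QCThresholds = field(default_factory=qcmod.QCThresholds)
    error_rate: float = 0.01
    accept_prob: float = 0.90
    cohort_rule: par.CohortRule = field(default_factory=par.CohortRule)
    mortality: float = 0.198
    n_iter: int = 1000
    n_perm: int = 100
    seed: int = 0
    run_qc: bool = True
    run_assign: bool = True
    run_accumulate: bool = True
    run_success: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = syn.SimConfig(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in raw.pop("sim", {}).items()})
        qc = qcmod.QCThresholds(**raw.pop("qc", {}))
        rule = par.CohortRule(**raw.pop("cohort_rule", {}))
        return cls(sim=sim, qc=qc, cohort_rule=rule, **raw)


def run_all(config: RunConfig) -> dict:
    """Run the pipeline end to end, writing CSV/JSON artifacts to
    ``config.out_dir``. Returns the in-memory results dictionary."""
    t0 = time.time()
    os.makedirs(config.out_dir, exist_ok=True)
    results: dict = {}

    if config.simulate:
        log.info("simulating population")
        truth, metadata, gm = syn.simulate_population(config.sim)
        results["truth"] = truth
    else:
        if not (config.genotypes_path and config.metadata_path):
            raise FileNotFoundError("genotypes_path and metadata_path required "
                                    "when simulate is off")
        gm = read_genotype_csv(config.genotypes_path, config.loci_path)
        metadata = read_metadata(config.metadata_path)

    if config.run_qc:
        log.info("QC on %d samples x %d loci", gm.n_samples, gm.n_loci)
        report = qcmod.run_qc(gm, config.qc, seed=config.seed)
        results["qc"] = report
        gm = report.retained
        with open(os.path.join(config.out_dir, "qc_report.json"), "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, default=str)

    assignments = None
    if config.run_assign:
        log.info("parentage on %d samples", gm.n_samples)
        assignments = par.assign_all(
            gm, metadata,
            error_rate=config.error_rate,
            accept_prob=config.accept_prob,
            rule=config.cohort_rule,
        )
        assignments = par.infer_unsampled_mates(
            assignments, gm, error_rate=config.error_rate
        )
        results["assignments"] = assignments
        assignments.to_csv(
            os.path.join(config.out_dir, "pedigree.csv"), index=False, na_rep="NA"
        )
        results["assignment_summary"] = summarize_assignments(assignments)
        results["assignment_summary"].to_csv(
            os.path.join(config.out_dir, "assignment_summary.csv"), index=False
        )
        mates = pd.concat(
            [par.count_mates(assignments, y)
             for y in sorted(assignments.cohort_year.unique())],
            ignore_index=True,
        )
        results["mate_summary"] = summarize_mates(mates) if len(mates) else None
        if results["mate_summary"] is not None:
            results["mate_summary"].to_csv(
                os.path.join(config.out_dir, "mate_summary.csv"), index=False
            )
        results["overlap"] = summarize_overlap(assignments)
        with open(os.path.join(config.out_dir, "parent_overlap.json"), "w") as fh:
            json.dump(results["overlap"], fh, indent=2)

    if config.run_accumulate and assignments is not None:
        ests = []
        for y in sorted(assignments.cohort_year.unique()):
            e = acc.estimate_ns(assignments, int(y), n_perm=config.n_perm,
                                seed=config.seed)
            ests.append(
                {"year": int(y), "s_obs": e.s_obs, "n": e.n, "f1": e.f1,
                 "f2": e.f2, "chao": e.chao, "chao_se": e.chao_se,
                 "jack1": e.jack1, "jack1_se": e.jack1_se}
            )
        results["ns_estimates"] = pd.DataFrame(ests)
        results["ns_estimates"].to_csv(
            os.path.join(config.out_dir, "ns_estimates.csv"), index=False
        )

    if config.run_success and assignments is not None:
        log.info("reproductive-success models (%d iterations)", config.n_iter)
        table = suc.build_success_table(metadata, assignments)
        results["success_table"] = table
        table.to_csv(os.path.join(config.out_dir, "success_table.csv"),
                     index=False, na_rep="NA")
        uni = {}
        for sex in ("F", "M"):
            for trait in ("tl", "age", "growth"):
                try:
                    s = suc.run_univariate(
                        table, trait, sex, n_iter=config.n_iter,
                        rate=config.mortality, master_seed=config.seed,
                    )
                except RuntimeError as exc:
                    log.warning("univariate %s/%s failed: %s", trait, sex, exc)
                    continue
                uni[f"{sex}:{trait}"] = s
        results["univariate"] = uni
        sel = {}
        for sex in ("F", "M"):
            try:
                sel[sex] = suc.select_model(
                    table, sex, n_iter=config.n_iter,
                    rate=config.mortality, master_seed=config.seed,
                )
            except RuntimeError as exc:
                log.warning("model selection for %s failed: %s", sex, exc)
        results["selection"] = sel
        _write_success_tables(uni, sel, config.out_dir)

    provenance = {
        "seed": config.seed,
        "mortality": config.mortality,
        "n_iter": config.n_iter,
        "qc_thresholds": vars(config.qc),
        "error_rate": config.error_rate,
        "accept_prob": config.accept_prob,
        "cohort_rule": asdict(config.cohort_rule),
        "simulated": config.simulate,
        "sim_config": asdict(config.sim) if config.simulate else None,
        "elapsed_s": round(time.time() - t0, 2),
    }
    with open(os.path.join(config.out_dir, "provenance.json"), "w") as fh:
        json.dump(provenance, fh, indent=2, default=str)
    results["provenance"] = provenance
    log.info("done in %.1fs", provenance["elapsed_s"])
    return results


def _write_success_tables(uni: dict, sel: dict, out_dir: str) -> None:
    rows = []
    for key, s in uni.items():
        sex, trait = key.split(":")
        med = s.medians
        slope_row = med.index[-1]
        rows.append(
            {
                "model": trait, "sex": sex,
                "intercept": med.at["intercept", "coef"],
                "se_int": med.at["intercept", "se"],
                "slope": med.at[slope_row, "coef"],
                "se_slope": med.at[slope_row, "se"],
                "p_slope": med.at[slope_row, "wald_p"],
                "or_slope": med.at[slope_row, "odds_ratio"],
                "or_lo95": med.at[slope_row, "or_lo95"],
                "or_hi95": med.at[slope_row, "or_hi95"],
                "r2": s.median_r2, "n": s.median_n,
            }
        )
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "univariate_models.csv"),
                              index=False)
    srows = []
    for sex, s in sel.items():
        srows.append(
            {
                "sex": sex,
                "selected_model": s.selected_model,
                "terms": "+".join(suc.CANDIDATE_MODELS[s.selected_model]) or "null",
                "tally": s.tally[s.selected_model],
                "r2": s.median_r2,
                "delta_bic": s.median_delta_bic,
                "bic_weight": s.median_bic_weight,
                "n": s.median_n,
            }
        )
    pd.DataFrame(srows).to_csv(os.path.join(out_dir, "model_selection.csv"),
                               index=False)
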