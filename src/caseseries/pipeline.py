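"""Configuration-driven end-to-end analysis.

Stages, in order: validation -> direction alignment -> PPCA imputation
(patients and controls imputed under separately fitted models, so patient
pathology never shapes control imputations) -> per-test measure collapsing
-> group PCA with varimax rotation and control-norm projection -> domain
composites -> per-patient Bayesian deficit tests -> deficit-pattern table
-> pairwise dissociation tests -> factor/pattern overlay.

Every stochastic stage receives a seed derived from the master seed via a
spawn-key fan-out, so adding a stage never perturbs earlier streams, and
re-running with the same inputs is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortTable, write_results
from .preprocess import collapse_test_measures, orient_measures, zscore_to_reference
from .ppca import fit_ppca, impute, select_components_cv
from .factors import (extract_components, factor_scores, project_controls,
                      rotate_solution)
from .composites import (composite_scores, deficit_flags, deficit_tests,
                         dissociation_tests, overlay_report, pattern_table)

__all__ = ["RunConfig", "AnalysisBundle", "run_full_analysis"]


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    alpha: float = 0.05
    deficit_tail: str = "lower"
    diff_tail: str = "two"
    n_mc: int = 10_000
    k_grid: tuple[int, ...] = (1, 2, 3, 4, 5)
    folds: int = 5
    repetitions: int = 10
    cutoff_mode: str = "score_sd"
    composite_method: str = "pca_weighted"
    covariates: tuple[str, ...] = ("age",)

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def _stage_seed(master: int, stage: int) -> int:
    ss = np.random.SeedSequence(master, spawn_key=(stage,))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class AnalysisBundle:
    tables: dict[str, pd.DataFrame]
    solution_summary: dict
    config: RunConfig

    def write(self, path: str | Path) -> dict:
        manifest = write_results(self.tables, path)
        summary = dict(self.solution_summary)
        summary["config"] = asdict(self.config)
        with open(Path(path) / "solution.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=float)
            fh.write("\n")
        return manifest


def _impute_group(cohort: CohortTable, mask: np.ndarray, cfg: RunConfig,
                  stage: int) -> tuple[np.ndarray, dict]:
    """CV-select k and impute one participant group; identity if complete."""
    sub_vals = cohort.values[mask]
    sub_obs = cohort.observed[mask]
    info: dict = {"n_missing": int((~sub_obs).sum())}
    if sub_obs.all():
        info["chosen_k"] = None
        return sub_vals.copy(), info
    p = sub_vals.shape[1]
    k_grid = [k for k in cfg.k_grid if k < p]
    report = select_components_cv(sub_vals, sub_obs, k_grid=k_grid,
                                  folds=cfg.folds, repetitions=cfg.repetitions,
                                  seed=_stage_seed(cfg.seed, stage))
    model = fit_ppca(sub_vals, sub_obs, k=report.chosen_k,
                     seed=_stage_seed(cfg.seed, stage + 1))
    info.update(report.to_dict())
    return impute(sub_vals, sub_obs, model), info


def run_full_analysis(cohort: CohortTable, config: RunConfig = RunConfig()) -> AnalysisBundle:
    """Run the whole case-series analysis on a validated cohort."""
    cohort.require_analysable()
    cohort = orient_measures(cohort)
    pat = cohort.is_patient
    ctrl = ~pat

    # -- imputation (separate models per group) --------------------------
    pat_vals, pat_cv = _impute_group(cohort, pat, config, stage=10)
    ctrl_vals, ctrl_cv = _impute_group(cohort, ctrl, config, stage=20)
    full = cohort.values.copy()
    full[pat] = pat_vals
    full[ctrl] = ctrl_vals
    completed = cohort.with_values(full, observed=np.ones_like(cohort.observed))

    # -- group PCA on patients, controls projected -----------------------
    pca_scores = collapse_test_measures(completed, fit_mask=pat)
    z_all = zscore_to_reference(pca_scores, pat, reference_name="patients")
    z_pat = z_all.rows(pat)
    z_ctrl = z_all.rows(ctrl)
    solution = rotate_solution(extract_components(z_pat))
    fs_pat = factor_scores(solution, z_pat)
    fs_ctrl = project_controls(solution, z_ctrl, cutoff_mode=config.cutoff_mode)
    fs_pat.control_mean = fs_ctrl.control_mean
    fs_pat.control_sd = fs_ctrl.control_sd
    fs_pat.cutoff = fs_ctrl.cutoff

    # -- composites and single-case classification -----------------------
    comp_scores = collapse_test_measures(completed)
    composites = composite_scores(comp_scores, completed,
                                  method=config.composite_method)
    deficits = deficit_tests(composites, completed,
                             covariates=config.covariates, alpha=config.alpha,
                             tail=config.deficit_tail, n_mc=config.n_mc,
                             seed=_stage_seed(config.seed, 30))
    flags = deficit_flags(deficits)
    patterns = pattern_table(flags, completed)
    dissoc = dissociation_tests(composites, completed, deficits,
                                covariates=config.covariates,
                                alpha=config.alpha, tail=config.diff_tail,
                                n_mc=config.n_mc,
                                seed=_stage_seed(config.seed, 40))
    overlay = overlay_report(fs_pat, flags, completed)

    # -- assemble ---------------------------------------------------------
    load_df = solution.loadings_frame().reset_index(names="test_id")
    score_rows = []
    groups = {p.participant_id: p.group.value for p in completed.participants}
    for fs in (fs_pat, fs_ctrl):
        df = fs.to_frame().reset_index(names="participant_id")
        df["group"] = df["participant_id"].map(groups)
        score_rows.append(df)
    scores_df = pd.concat(score_rows, ignore_index=True)

    comp_df = composites.values.reset_index(names="participant_id")
    comp_df["group"] = comp_df["participant_id"].map(groups)

    summary = {
        "kmo": solution.kmo,
        "n_retained": solution.n_retained,
        "eigenvalues": [float(x) for x in solution.eigenvalues],
        "var_explained": [float(x) for x in solution.var_explained],
        "total_var_explained": solution.total_var_explained,
        "control_mean": [float(x) for x in fs_ctrl.control_mean],
        "control_sd": [float(x) for x in fs_ctrl.control_sd],
        "cutoff": [float(x) for x in fs_ctrl.cutoff],
        "cv_patients": pat_cv,
        "cv_controls": ctrl_cv,
    }
    tables = {
        "loadings": load_df,
        "factor_scores": scores_df,
        "composites": comp_df,
        "deficits": deficits,
        "deficit_flags": flags,
        "pattern_counts": patterns,
        "dissociations": dissoc,
        "overlay": overlay,
    }
    return AnalysisBundle(tables=tables, solution_summary=summary, config=config)
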