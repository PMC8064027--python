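"""Domain composite scores and the deficit / dissociation classification.

Each of the three composite domains (words, objects, faces) is summarized
by one weighted average of its matched tests over controls *and* patients;
each patient's composite is then compared to the control sample with the
Bayesian deficit test conditioned on age, the per-domain deficit flags are
collapsed into an 8-way pattern label (NONE, W, O, F, WO, WF, OF, WOF), and
patients with at least one deficit are tested for pairwise dissociations:
a putatively classical dissociation requires (1) a significant deficit on
task X, (2) task Y within the control range, and (3) a significant
standardized X-Y difference relative to the controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, COMPOSITE_DOMAINS, CohortValidationError
from .preprocess import ScoreMatrix
from .factors import FactorScores
from .singlecase import btd_cov, bsdt_cov

__all__ = [
    "CompositeScores",
    "composite_scores",
    "deficit_tests",
    "pattern_label",
    "pattern_table",
    "dissociation_tests",
    "overlay_report",
    "pooled_t_from_summary",
    "PATTERN_LABELS",
]

PATTERN_LABELS = ("NONE", "W", "O", "F", "WO", "WF", "OF", "WOF")
_DOMAIN_KEY = {"word": "W", "object": "O", "face": "F"}
DEFAULT_PAIRS = (("word", "face"), ("word", "object"), ("object", "face"))


@dataclass
class CompositeScores:
    """Per-participant word/object/face composite values plus the weighting
    table that produced them."""

    participant_ids: list[str]
    values: pd.DataFrame            # index participant_id, columns domains
    method: str                     # pca_weighted | rank_sum
    weights: pd.DataFrame           # loading table (pca) or rank meta

    def domain(self, domain: str) -> np.ndarray:
        return self.values[domain].to_numpy()


def _domain_map(matrix: ScoreMatrix, cohort: CohortTable) -> dict[str, list[int]]:
    by_test = {t.test_id: t for t in cohort.tests}
    out: dict[str, list[int]] = {d: [] for d in COMPOSITE_DOMAINS}
    for j, tid in enumerate(matrix.test_ids):
        t = by_test.get(tid)
        if t is not None and t.in_composite:
            out[t.domain].append(j)
    for d, cols in out.items():
        if not cols:
            raise CohortValidationError(f"domain {d!r} has no composite tests")
    return out


def composite_scores(matrix: ScoreMatrix, cohort: CohortTable,
                     method: str = "pca_weighted") -> CompositeScores:
    """Build one composite per domain from the schema's in_composite tests.

    pca_weighted: standardize the domain's tests over all subjects, take
    the first unrotated principal component score (sign-fixed so the mean
    loading is positive, i.e. higher = better), rescaled to unit variance.
    rank_sum: rank every subject per test (mean rank on ties, higher =
    better) and average the ranks within the domain.
    """
    if not np.isfinite(matrix.values).all():
        raise CohortValidationError("composite scores require a complete matrix")
    dmap = _domain_map(matrix, cohort)
    n = len(matrix.participant_ids)
    cols = {}
    wrows = []
    for d in COMPOSITE_DOMAINS:
        block = matrix.values[:, dmap[d]]
        names = [matrix.test_ids[j] for j in dmap[d]]
        sds = block.std(axis=0, ddof=1)
        if np.all(sds <= 0):
            raise CohortValidationError(f"domain {d!r}: all tests zero-variance")
        if np.any(sds <= 0):
            bad = names[int(np.argmax(sds <= 0))]
            raise CohortValidationError(f"zero-variance test {bad!r} in domain {d!r}")
        if method == "pca_weighted":
            Z = (block - block.mean(axis=0)) / sds
            if Z.shape[1] == 1:
                cols[d] = Z[:, 0]
                wrows.append({"domain": d, "test_id": names[0], "weight": 1.0})
                continue
            R = np.corrcoef(Z, rowvar=False)
            lam, vec = np.linalg.eigh(R)
            lead = vec[:, -1]
            if lead.mean() < 0:
                lead = -lead
            cols[d] = (Z @ lead) / np.sqrt(lam[-1])
            for nm, w in zip(names, lead):
                wrows.append({"domain": d, "test_id": nm, "weight": float(w)})
        elif method == "rank_sum":
            ranks = np.column_stack([
                stats.rankdata(block[:, jj]) for jj in range(block.shape[1])
            ])
            cols[d] = ranks.mean(axis=1)
            for nm in names:
                wrows.append({"domain": d, "test_id": nm, "weight": 1.0})
        else:
            raise ValueError(f"unknown composite method {method!r}")
    values = pd.DataFrame(cols, index=matrix.participant_ids)
    return CompositeScores(
        participant_ids=list(matrix.participant_ids),
        values=values, method=method,
        weights=pd.DataFrame(wrows),
    )


def _covariate_matrix(cohort: CohortTable, covariates: tuple[str, ...],
                      mask: np.ndarray) -> np.ndarray:
    cols = []
    for cov in covariates:
        vals = []
        for p, keep in zip(cohort.participants, mask):
            if not keep:
                continue
            v = getattr(p, cov)
            if v is None or not np.isfinite(v):
                raise CohortValidationError(
                    f"participant {p.participant_id!r}: covariate {cov!r} is "
                    "missing but required for a covariate-adjusted test"
                )
            vals.append(float(v))
        cols.append(vals)
    return np.array(cols, dtype=float).T if cols else np.empty((int(mask.sum()), 0))


def deficit_tests(composites: CompositeScores, cohort: CohortTable,
                  covariates: tuple[str, ...] = ("age",), alpha: float = 0.05,
                  tail: str = "lower", n_mc: int = 10_000,
                  seed: int | None = 0) -> pd.DataFrame:
    """Per-patient, per-domain Bayesian deficit tests against the controls.

    Returns one row per (patient, domain) with p, abnormality percentile
    and CI, effect size, and the deficit flag p < alpha.
    """
    ctrl = ~cohort.is_patient
    pat = cohort.is_patient
    Xc = _covariate_matrix(cohort, covariates, ctrl)
    Xp = _covariate_matrix(cohort, covariates, pat)
    ss = np.random.SeedSequence(seed)
    rows = []
    pat_ids = [p.participant_id for p, m in zip(cohort.participants, pat) if m]
    pid_index = {pid: i for i, pid in enumerate(composites.participant_ids)}
    ctrl_rows = [pid_index[p.participant_id]
                 for p, m in zip(cohort.participants, ctrl) if m]
    for i, pid in enumerate(pat_ids):
        for d in COMPOSITE_DOMAINS:
            y = composites.values[d].to_numpy()[ctrl_rows]
            y_star = composites.values[d].loc[pid]
            sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            res = btd_cov(y, Xc, float(y_star), Xp[i], tail=tail,
                          n_mc=n_mc, seed=sub_seed)
            rows.append({
                "participant_id": pid, "domain": d, "p": res.p,
                "abnormality_pct": res.abnormality_pct,
                "ci_low": res.abnormality_ci[0], "ci_high": res.abnormality_ci[1],
                "z_ccc": res.z_ccc, "deficit": bool(res.p < alpha),
            })
    return pd.DataFrame(rows)


def pattern_label(word: bool, obj: bool, face: bool) -> str:
    """Deterministic 8-way label from the three domain flags."""
    key = ("W" if word else "") + ("O" if obj else "") + ("F" if face else "")
    return key if key else "NONE"


def deficit_flags(deficits: pd.DataFrame) -> pd.DataFrame:
    """Pivot the deficit table to one row per patient with the three flags
    and the pattern label."""
    wide = deficits.pivot(index="participant_id", columns="domain", values="deficit")
    wide = wide[list(COMPOSITE_DOMAINS)].astype(bool)
    wide["label"] = [
        pattern_label(w, o, f)
        for w, o, f in zip(wide["word"], wide["object"], wide["face"])
    ]
    return wide.reset_index()


def pattern_table(flags: pd.DataFrame, cohort: CohortTable | None = None) -> pd.DataFrame:
    """Frequency of the 8 deficit patterns, optionally split by lesion
    laterality group; counts always partition the patient set."""
    flags = flags.copy()
    if cohort is not None:
        gmap = {p.participant_id: p.group.value for p in cohort.participants}
        flags["group"] = flags["participant_id"].map(gmap)
    else:
        flags["group"] = "all"
    rows = []
    for lab in PATTERN_LABELS:
        row = {"label": lab}
        sel = flags["label"] == lab
        for g in sorted(flags["group"].unique()):
            row[g] = int((sel & (flags["group"] == g)).sum())
        row["total"] = int(sel.sum())
        rows.append(row)
    return pd.DataFrame(rows)


def dissociation_tests(composites: CompositeScores, cohort: CohortTable,
                       deficits: pd.DataFrame,
                       pairs=DEFAULT_PAIRS,
                       covariates: tuple[str, ...] = ("age",),
                       alpha: float = 0.05, tail: str = "two",
                       n_mc: int = 10_000, seed: int | None = 0) -> pd.DataFrame:
    """Pairwise dissociation classification for patients with >=1 deficit.

    For each domain pair the more impaired task (smaller deficit p) plays
    task X.  Criteria: (1) X's deficit flag; (2) Y within the control range
    (deficit p >= alpha on Y); (3) the standardized X-Y difference differs
    from controls (Bayesian standardized difference test with the same
    covariates).  Labels: classical = 1 & 2 & 3; differential = both tasks
    impaired and 3; none otherwise.  Patients with no deficit anywhere are
    not tested (the classification's gating rule).
    """
    ctrl = ~cohort.is_patient
    pat = cohort.is_patient
    Xc = _covariate_matrix(cohort, covariates, ctrl)
    Xp = _covariate_matrix(cohort, covariates, pat)
    pid_index = {pid: i for i, pid in enumerate(composites.participant_ids)}
    ctrl_rows = [pid_index[p.participant_id]
                 for p, m in zip(cohort.participants, ctrl) if m]
    pat_ids = [p.participant_id for p, m in zip(cohort.participants, pat) if m]

    dmap = deficits.set_index(["participant_id", "domain"])
    ss = np.random.SeedSequence(seed)
    rows = []
    for i, pid in enumerate(pat_ids):
        flagged = any(bool(dmap.loc[(pid, d), "deficit"]) for d in COMPOSITE_DOMAINS)
        if not flagged:
            continue
        for a, bdom in pairs:
            pa = float(dmap.loc[(pid, a), "p"])
            pb = float(dmap.loc[(pid, bdom), "p"])
            x_dom, y_dom = (a, bdom) if pa <= pb else (bdom, a)
            c1 = bool(dmap.loc[(pid, x_dom), "deficit"])
            y_deficit = bool(dmap.loc[(pid, y_dom), "deficit"])
            c2 = not y_deficit
            Ypair = np.column_stack([
                composites.values[x_dom].to_numpy()[ctrl_rows],
                composites.values[y_dom].to_numpy()[ctrl_rows],
            ])
            case = np.array([
                composites.values[x_dom].loc[pid],
                composites.values[y_dom].loc[pid],
            ], dtype=float)
            sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            diff = bsdt_cov(Ypair, Xc, case, Xp[i], tail=tail,
                            n_mc=n_mc, seed=sub_seed)
            c3 = bool(diff.p_diff < alpha)
            if c1 and c2 and c3:
                label = "classical"
            elif c1 and y_deficit and c3:
                label = "differential"
            else:
                label = "none"
            rows.append({
                "participant_id": pid, "pair": f"{a}-{bdom}",
                "task_x": x_dom, "task_y": y_dom,
                "criterion1_x_deficit": c1,
                "criterion2_y_in_range": c2,
                "criterion3_diff_significant": c3,
                "p_diff": diff.p_diff, "z_x": diff.z_x, "z_y": diff.z_y,
                "rho": diff.rho, "label": label,
            })
    cols = ["participant_id", "pair", "task_x", "task_y",
            "criterion1_x_deficit", "criterion2_y_in_range",
            "criterion3_diff_significant", "p_diff", "z_x", "z_y", "rho", "label"]
    return pd.DataFrame(rows, columns=cols)


def overlay_report(fscores: FactorScores, flags: pd.DataFrame,
                   cohort: CohortTable) -> pd.DataFrame:
    """Join patient factor scores with deficit patterns: one row per patient
    with factor coordinates, laterality, lesion volume, pattern label, and
    per-factor below-cutoff flags."""
    if fscores.cutoff is None:
        raise ValueError("factor scores lack control norms; project controls first")
    sf = fscores.to_frame()
    flag_idx = flags.set_index("participant_id")
    missing = [pid for pid in sf.index if pid not in flag_idx.index]
    extra = [pid for pid in flag_idx.index if pid not in sf.index]
    if missing or extra:
        raise ValueError(
            f"participant mismatch between factor scores and patterns: "
            f"missing={missing[:5]}, extra={extra[:5]}"
        )
    meta = {p.participant_id: p for p in cohort.participants}
    rows = []
    for pid in sf.index:
        p = meta[pid]
        row = {"participant_id": pid, "group": p.group.value,
               "lesion_volume": p.lesion_volume,
               "label": flag_idx.loc[pid, "label"]}
        for f in range(sf.shape[1]):
            val = sf.iloc[:, f].loc[pid]
            row[f"factor{f + 1}"] = float(val)
            row[f"factor{f + 1}_below_cutoff"] = bool(val < fscores.cutoff[f])
        rows.append(row)
    return pd.DataFrame(rows)


def pooled_t_from_summary(m1: float, s1: float, n1: int,
                          m2: float, s2: float, n2: int) -> tuple[float, int, float]:
    """Pooled-variance two-sample t from summary statistics.

    Returns (t, df, two-tailed p) with df = n1 + n2 - 2; used for group
    demographic comparisons reported as mean (SD) per subgroup.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if s1 < 0 or s2 < 0 or (s1 == 0 and s2 == 0):
        raise ValueError("invalid SDs")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (m1 - m2) / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), int(df), p
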