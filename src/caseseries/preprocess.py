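"""Direction alignment, per-test measure collapsing, and reference-group
standardization.

These steps bring a raw cohort onto a single score per test, uniformly
oriented so that higher is always better, standardized against a chosen
reference group (for the group PCA: the patients themselves, so that 0 on
every factor is the patient-group mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable, Direction, Measure, TestSpec, CohortValidationError

__all__ = ["ScoreMatrix", "orient_measures", "collapse_test_measures", "zscore_to_reference"]


@dataclass
class ScoreMatrix:
    """Participants x tests real matrix, one column per test, all columns
    oriented higher-is-better."""

    participant_ids: list[str]
    test_ids: list[str]
    values: np.ndarray
    #: per-column (mean, sd) of the standardization reference, or None
    reference_stats: pd.DataFrame | None = None
    reference_group: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.participant_ids), len(self.test_ids)):
            raise ValueError("ScoreMatrix shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.participant_ids, columns=self.test_ids
        )

    def rows(self, mask: np.ndarray) -> "ScoreMatrix":
        mask = np.asarray(mask, dtype=bool)
        return ScoreMatrix(
            participant_ids=[p for p, m in zip(self.participant_ids, mask) if m],
            test_ids=list(self.test_ids),
            values=self.values[mask].copy(),
            reference_stats=self.reference_stats,
            reference_group=self.reference_group,
        )


def orient_measures(cohort: CohortTable) -> CohortTable:
    """Negate every lower-is-better measure so all columns read
    higher-is-better; directions in the returned schema are rewritten, which
    makes a second application a no-op."""
    values = cohort.values.copy()
    new_tests = []
    j = 0
    for t in cohort.tests:
        new_measures = []
        for m in t.measures:
            if m.direction is Direction.LOWER_IS_BETTER:
                values[:, j] = -values[:, j]
                new_measures.append(Measure(m.measure_id, Direction.HIGHER_IS_BETTER))
            else:
                new_measures.append(m)
            j += 1
        new_tests.append(
            TestSpec(
                test_id=t.test_id,
                domain=t.domain,
                measures=tuple(new_measures),
                in_composite=t.in_composite,
            )
        )
    return CohortTable(
        participants=list(cohort.participants),
        tests=new_tests,
        values=values,
        observed=cohort.observed.copy(),
    )


def _zscore_columns(block: np.ndarray, names: list[str]) -> np.ndarray:
    mu = block.mean(axis=0)
    sd = block.std(axis=0, ddof=1)
    for k, s in enumerate(sd):
        if not s > 0:
            raise CohortValidationError(f"zero-variance measure {names[k]!r}")
    return (block - mu) / sd


def _anchor_index(test: TestSpec) -> int:
    """Measure used to fix the sign of a collapsed score: the accuracy
    measure if present, else the first measure in sorted measure_id order
    (so the rule does not depend on column order)."""
    ids = list(test.measure_ids)
    if "acc" in ids:
        return ids.index("acc")
    return ids.index(sorted(ids)[0])


def collapse_test_measures(cohort: CohortTable,
                           fit_mask: np.ndarray | None = None) -> ScoreMatrix:
    """Reduce each multi-measure test to a single score via the first
    unrotated principal component of its standardized measures.

    Runs after imputation: every cell must be observed.  Single-measure
    tests pass through as z-scores.  Component scores are scaled to unit
    variance and sign-fixed so the accuracy measure loads positively.

    ``fit_mask`` selects the rows used to estimate the standardization and
    component weights (default: all rows); the transform is applied to
    every row, so e.g. controls can be collapsed with patient-derived
    weights for projection into the patient factor space.
    """
    if not cohort.observed.all():
        raise CohortValidationError(
            "collapse_test_measures requires a fully observed matrix; impute first"
        )
    if cohort.n_participants < 2:
        raise CohortValidationError("collapse requires >=2 participants")
    if fit_mask is None:
        fit_mask = np.ones(cohort.n_participants, dtype=bool)
    fit_mask = np.asarray(fit_mask, dtype=bool)
    if fit_mask.sum() < 2:
        raise CohortValidationError("collapse fit subset needs >=2 rows")
    out = np.empty((cohort.n_participants, len(cohort.tests)))
    j = 0
    for tix, t in enumerate(cohort.tests):
        m = len(t.measures)
        names = [f"{t.test_id}__{mid}" for mid in t.measure_ids]
        block = cohort.values[:, j : j + m]
        fit = block[fit_mask]
        mu = fit.mean(axis=0)
        sd = fit.std(axis=0, ddof=1)
        for kk, s in enumerate(sd):
            if not s > 0:
                raise CohortValidationError(f"zero-variance measure {names[kk]!r}")
        Z = (block - mu) / sd
        if m == 1:
            out[:, tix] = Z[:, 0]
        else:
            R = np.corrcoef(Z[fit_mask], rowvar=False)
            lam, vec = np.linalg.eigh(R)
            lead = vec[:, -1]
            anchor = _anchor_index(t)
            if lead[anchor] < 0:
                lead = -lead
            lam1 = lam[-1]
            # unit-variance scaling; PC score variance is the eigenvalue
            out[:, tix] = (Z @ lead) / np.sqrt(lam1)
        j += m
    return ScoreMatrix(
        participant_ids=cohort.participant_ids,
        test_ids=[t.test_id for t in cohort.tests],
        values=out,
    )


def zscore_to_reference(matrix: ScoreMatrix, reference_mask: np.ndarray,
                        reference_name: str = "reference") -> ScoreMatrix:
    """Standardize every column by the mean and SD (ddof=1) of the reference
    subgroup; the reference stats are recorded on the result."""
    mask = np.asarray(reference_mask, dtype=bool)
    if mask.sum() < 2:
        raise CohortValidationError("reference subgroup needs >=2 members")
    ref = matrix.values[mask]
    mu = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=1)
    for k, s in enumerate(sd):
        if not s > 0:
            raise CohortValidationError(
                f"reference sd is zero for test {matrix.test_ids[k]!r}"
            )
    stats = pd.DataFrame(
        {"test_id": matrix.test_ids, "ref_mean": mu, "ref_sd": sd}
    )
    return ScoreMatrix(
        participant_ids=list(matrix.participant_ids),
        test_ids=list(matrix.test_ids),
        values=(matrix.values - mu) / sd,
        reference_stats=stats,
        reference_group=reference_name,
    )
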