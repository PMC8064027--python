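"""Synthetic cohort generator with ground truth for recovery testing.

Real patient-level data from this kind of stroke case-series cannot be
archived, so the pipeline is validated on simulated cohorts that carry the
statistical structure the analysis assumes:

* a two-dimensional latent ability space (a word/object factor and a
  face/object factor) with a configurable correlation between the two;
* per-test loadings that give words and faces nearly pure factor
  signatures and objects a split signature;
* age-dependence of every test score (performance declines with age);
* lesion-laterality group effects — left-hemisphere lesions depress the
  word/object factor, right-hemisphere the face/object factor, bilateral
  both — scaled by a lognormal lesion volume;
* optional planted category-selective cases: patients whose lesion effect
  is replaced by a pure deficit of a stated size (in control-SD units) on
  one domain's tests only, emulating a selective impairment that bypasses
  the shared factors;
* paired accuracy/RT measures with a stated within-test correlation;
* missing-completely-at-random cells at a configurable rate.

Every generated quantity (latents, shifts, planted labels, loading table)
is returned as ground truth so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import CohortTable, Group, ParticipantRecord, TestSpec, default_battery
from .factors import tucker_congruence

__all__ = ["GeneratorConfig", "SyntheticTruth", "generate_cohort", "recovery_report"]

# per-domain generating loadings (factor1 = word/object, factor2 = face/object)
DEFAULT_LOADINGS = {
    "word": (0.8, 0.1),
    "object": (0.5, 0.5),
    "face": (0.1, 0.8),
    "low_level": (0.3, 0.3),
    "mixed": (0.4, 0.4),
}

# residual noise SD per domain; word tests have the tightest control
# distribution (reading is near-ceiling for literate adults), faces the
# loosest, matching the variability asymmetry the analysis must cope with
DEFAULT_NOISE_SD = {
    "word": 0.25,
    "object": 0.40,
    "face": 0.55,
    "low_level": 0.50,
    "mixed": 0.45,
}


@dataclass(frozen=True)
class GeneratorConfig:
    n_controls: int = 46
    n_left: int = 32
    n_right: int = 23
    n_bilateral: int = 9
    factor_corr: float = 0.3
    age_effect: float = -0.25          # per unit z(age), every test
    delta_left: float = 1.2            # factor-1 depression, left lesions
    delta_right: float = 1.2           # factor-2 depression, right lesions
    delta_bilateral: float = 1.2       # both factors, bilateral lesions
    volume_scaling: float = 0.5        # lesion effect ~ (vol/ref)^scaling
    within_test_corr: float = 0.7      # accuracy-RT correlation within a test
    #: (domain, effect size in control SD, count) of planted selective cases
    planted_cases: tuple[tuple[str, float, int], ...] = (("word", 3.0, 4),)
    missing_rate: float = 0.03
    loadings: dict = field(default_factory=lambda: dict(DEFAULT_LOADINGS))
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))

    def __post_init__(self):
        for n in (self.n_controls, self.n_left, self.n_right, self.n_bilateral):
            if n < 0:
                raise ValueError("group counts must be >= 0")
        if not 0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must be in [0, 0.5)")
        if not abs(self.factor_corr) < 1:
            raise ValueError("|factor_corr| must be < 1")

    @property
    def n_patients(self) -> int:
        return self.n_left + self.n_right + self.n_bilateral

    def null(self) -> "GeneratorConfig":
        """A copy with all group effects and planted cases removed:
        patients and controls are exchangeable by construction."""
        return replace(self, delta_left=0.0, delta_right=0.0,
                       delta_bilateral=0.0, planted_cases=())


@dataclass
class SyntheticTruth:
    per_participant: pd.DataFrame   # latents, shifts, planted labels
    loading_table: pd.DataFrame     # test_id, loading1, loading2, noise_sd
    config: GeneratorConfig
    seed: int

    @property
    def planted_ids(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        df = self.per_participant
        for d in df.loc[df.planted_domain != "", "planted_domain"].unique():
            out[d] = df.loc[df.planted_domain == d, "participant_id"].tolist()
        return out


# volume reference for the effect scaling (cm^3); roughly the patient-wide
# mean lesion volume the generator targets
_VOL_REF = 37.0
_VOL_MEDIAN = {"left": 32.0, "right": 35.0, "bilateral": 61.0}
_AGE_MEAN, _AGE_SD = 61.0, 14.0


def _control_test_sd(l1: float, l2: float, rho: float, gamma: float,
                     noise: float) -> float:
    """Analytic control-group SD of a test's underlying score."""
    return float(np.sqrt(l1 ** 2 + l2 ** 2 + 2 * rho * l1 * l2
                         + gamma ** 2 + noise ** 2))


def generate_cohort(config: GeneratorConfig = GeneratorConfig(), seed: int = 0,
                    battery: list[TestSpec] | None = None,
                    ) -> tuple[CohortTable, SyntheticTruth]:
    """Generate a cohort plus its ground truth; deterministic given seed."""
    if battery is None:
        battery = default_battery()
    rng = np.random.default_rng(seed)
    groups = ([Group.CONTROL] * config.n_controls
              + [Group.LEFT] * config.n_left
              + [Group.RIGHT] * config.n_right
              + [Group.BILATERAL] * config.n_bilateral)
    n = len(groups)
    n_pat = config.n_patients

    # demographics
    age = np.clip(rng.normal(61.0, 14.0, size=n), 25.0, 92.0)
    education = np.clip(rng.normal(14.5, 2.5, size=n), 8.0, 22.0)
    z_age = (age - _AGE_MEAN) / _AGE_SD
    volume = np.full(n, np.nan)
    tss = np.full(n, np.nan)
    for i, g in enumerate(groups):
        if g is Group.CONTROL:
            continue
        volume[i] = np.exp(rng.normal(np.log(_VOL_MEDIAN[g.value]), 0.8))
        tss[i] = np.exp(rng.normal(np.log(40.0), 0.9))

    # latent abilities
    rho = config.factor_corr
    cov = np.array([[1.0, rho], [rho, 1.0]])
    latents = rng.multivariate_normal([0, 0], cov, size=n)

    # lesion group effects, scaled by lesion volume
    shift = np.zeros((n, 2))
    for i, g in enumerate(groups):
        if g is Group.CONTROL:
            continue
        sc = (volume[i] / _VOL_REF) ** config.volume_scaling
        if g is Group.LEFT:
            shift[i, 0] = -config.delta_left * sc
        elif g is Group.RIGHT:
            shift[i, 1] = -config.delta_right * sc
        else:
            shift[i, 0] = -config.delta_bilateral * sc
            shift[i, 1] = -config.delta_bilateral * sc

    # planted category-selective cases: replace the lesion effect with a
    # pure domain-specific deficit
    planted_domain = np.array([""] * n, dtype=object)
    planted_delta = np.zeros(n)
    patient_idx = np.arange(config.n_controls, n)
    pool = list(patient_idx)
    total_planted = sum(cnt for _, _, cnt in config.planted_cases)
    if total_planted > n_pat:
        raise ValueError(
            f"cannot plant {total_planted} cases among {n_pat} patients"
        )
    for domain, delta, count in config.planted_cases:
        if domain not in ("word", "object", "face"):
            raise ValueError(f"cannot plant cases in domain {domain!r}")
        chosen = rng.choice(pool, size=count, replace=False)
        for i in chosen:
            pool.remove(i)
            planted_domain[i] = domain
            planted_delta[i] = delta
            shift[i] = 0.0

    # test scores and measures
    lt_rows = []
    col_values = []
    col_labels = []
    w = config.within_test_corr
    for t in battery:
        l1, l2 = config.loadings[t.domain]
        noise = config.noise_sd[t.domain]
        gamma = config.age_effect
        sd_t = _control_test_sd(l1, l2, rho, gamma, noise)
        s = (latents[:, 0] + shift[:, 0]) * l1 + (latents[:, 1] + shift[:, 1]) * l2 \
            + gamma * z_age + rng.normal(0, noise, size=n)
        sel = planted_domain == t.domain
        s[sel] -= planted_delta[sel] * sd_t
        lt_rows.append({"test_id": t.test_id, "loading1": l1, "loading2": l2,
                        "noise_sd": noise, "control_sd": sd_t})
        for m in t.measures:
            if m.measure_id == "rt":
                eta = rng.normal(0, 1, size=n)
                speed = w * (s / sd_t) + np.sqrt(1 - w ** 2) * eta
                col_values.append(700.0 - 120.0 * speed)   # ms-like, lower better
            else:
                col_values.append(100.0 + 10.0 * s)        # points-like, higher better
            col_labels.append(f"{t.test_id}__{m.measure_id}")

    values = np.column_stack(col_values)

    # MCAR mask, kept analysable (every row and column observed somewhere)
    observed = np.ones_like(values, dtype=bool)
    if config.missing_rate > 0:
        for _ in range(200):
            observed = rng.random(values.shape) >= config.missing_rate
            if observed.any(axis=1).all() and observed.any(axis=0).all():
                break
        else:
            raise ValueError("could not draw an analysable missingness mask")

    participants = []
    for i, g in enumerate(groups):
        participants.append(ParticipantRecord(
            participant_id=f"{'c' if g is Group.CONTROL else 'p'}{i:03d}",
            group=g, age=float(age[i]), education=float(education[i]),
            lesion_volume=None if g is Group.CONTROL else float(volume[i]),
            time_since_stroke=None if g is Group.CONTROL else float(tss[i]),
        ))

    cohort = CohortTable(participants=participants, tests=list(battery),
                         values=values, observed=observed)
    truth = SyntheticTruth(
        per_participant=pd.DataFrame({
            "participant_id": [p.participant_id for p in participants],
            "group": [g.value for g in groups],
            "latent1": latents[:, 0], "latent2": latents[:, 1],
            "shift1": shift[:, 0], "shift2": shift[:, 1],
            "planted_domain": planted_domain, "planted_delta": planted_delta,
        }),
        loading_table=pd.DataFrame(lt_rows),
        config=config, seed=seed,
    )
    return cohort, truth


_LABEL_OF_DOMAIN = {"word": "W", "object": "O", "face": "F"}


def recovery_report(truth: SyntheticTruth,
                    flags: pd.DataFrame | None = None,
                    loadings: np.ndarray | None = None,
                    imputation_rmse: float | None = None,
                    baseline_rmse: float | None = None) -> pd.DataFrame:
    """Score pipeline outputs against the generating truth.

    Reports, where the corresponding input is supplied: planted-case
    sensitivity per domain (fraction recovered as that domain's *selective*
    pattern), the planted-vs-recovered label matrix, the false-positive
    rate among non-planted, non-shifted patients, minimum Tucker congruence
    between recovered and generating loadings, and the imputation-RMSE
    ratio against a column-mean baseline.  Metrics without inputs are NA.
    """
    rows: list[dict] = []
    tt = truth.per_participant

    if flags is not None:
        fl = flags.set_index("participant_id")
        for domain, ids in truth.planted_ids.items():
            want = _LABEL_OF_DOMAIN[domain]
            ids = [i for i in ids if i in fl.index]
            if not ids:
                rows.append({"metric": f"sensitivity_{domain}", "value": np.nan})
                continue
            hit = sum(fl.loc[i, "label"] == want for i in ids)
            rows.append({"metric": f"sensitivity_{domain}",
                         "value": hit / len(ids)})
            for lab in ("W", "O", "F", "NONE", "WOF", "WO", "WF", "OF"):
                cnt = sum(fl.loc[i, "label"] == lab for i in ids)
                rows.append({"metric": f"planted_{domain}_as_{lab}",
                             "value": cnt / len(ids)})
        if not truth.planted_ids:
            rows.append({"metric": "sensitivity", "value": np.nan})
        null_ids = tt.loc[
            (tt.group != "control") & (tt.planted_domain == "")
            & (tt.shift1 == 0.0) & (tt.shift2 == 0.0), "participant_id"]
        null_ids = [i for i in null_ids if i in fl.index]
        if null_ids:
            fp = sum(fl.loc[i, "label"] != "NONE" for i in null_ids)
            rows.append({"metric": "null_false_positive_rate",
                         "value": fp / len(null_ids)})
        else:
            rows.append({"metric": "null_false_positive_rate", "value": np.nan})
    if loadings is not None:
        gen = truth.loading_table[["loading1", "loading2"]].to_numpy()
        cong = tucker_congruence(np.asarray(loadings), gen)
        rows.append({"metric": "min_tucker_congruence",
                     "value": float(cong.min())})
    if imputation_rmse is not None:
        rows.append({"metric": "imputation_rmse", "value": imputation_rmse})
        if baseline_rmse is not None:
            rows.append({"metric": "imputation_rmse_ratio",
                         "value": imputation_rmse / baseline_rmse})
    return pd.DataFrame(rows, columns=["metric", "value"])
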