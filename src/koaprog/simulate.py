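"""Synthetic cohorts with known subtype structure, stages, and severity.

The generator emulates the statistical structure of a cross-sectional
knee-osteoarthritis cohort: each subject draws a subtype from configured
fractions and a stage uniformly over 0..S, takes the subtype's expected
piecewise-linear trajectory value at that stage per biomarker, adds
Gaussian noise on the z scale, and maps back to the raw measurement scale
(raw = control_mean + direction * z * control_sd, so downstream z-scoring
recovers the z values).  An ordinal severity grade 0..4 — the analog of the
Kellgren-Lawrence grade — is derived from the true stage by increasing
thresholds, optionally perturbed to an adjacent grade with a small flip
probability.  Demographics (age, gender, BMI, injury) are generated
independently of subtype by default, with optional subtype-linked shifts.

Control groups are Gaussian per biomarker: z-scoring, the only downstream
use, is exact for location-scale families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .events import (
    BiomarkerDef,
    EventSequence,
    EventSet,
    random_valid_order,
)
from .likelihood import expected_trajectory

#: Default demographic distributions, matched to published cohort summaries:
#: age ~ Normal(62, 9) years, BMI ~ Normal(29, 4.7) kg/m^2, 55% female,
#: 21% with a disabling knee injury history.
DEFAULT_DEMOGRAPHICS = {
    "age": (62.0, 9.0),
    "bmi": (29.0, 4.7),
    "gender": 0.55,
    "injury": 0.21,
}


@dataclass(frozen=True)
class SubtypeSpec:
    """Ground-truth subtype: an event ordering and its population fraction."""

    sequence: EventSequence
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError(f"fraction must lie in (0, 1], got {self.fraction}")


@dataclass
class CohortConfig:
    """Full specification of a synthetic cohort.

    ``severity_thresholds`` are strictly increasing stage cutpoints within
    [0, S]; grade = number of thresholds <= stage, giving grades 0..4 for
    four thresholds.
    """

    event_set: EventSet
    subtypes: Sequence[SubtypeSpec]
    biomarker_defs: Sequence[BiomarkerDef] | None = None
    n_subjects: int = 678
    n_controls: int = 100
    noise_sd: float = 1.0
    control_mean: Mapping[str, float] | float = 0.0
    control_sd: Mapping[str, float] | float = 1.0
    severity_thresholds: tuple[float, ...] = ()
    grade_flip_prob: float = 0.0
    demographics: Mapping = field(default_factory=lambda: dict(DEFAULT_DEMOGRAPHICS))
    subtype_demographic_shift: Mapping[int, Mapping[str, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_controls < 1:
            raise ValueError("n_subjects and n_controls must be positive")
        if not self.subtypes:
            raise ValueError("at least one subtype is required")
        frac = sum(s.fraction for s in self.subtypes)
        if abs(frac - 1.0) > 1e-12:
            raise ValueError(f"subtype fractions must sum to 1, got {frac}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for name in self.event_set.biomarkers:
            if self._sd(name) <= 0:
                raise ValueError(f"control_sd for {name!r} must be positive")
        if not self.severity_thresholds:
            self.severity_thresholds = default_severity_thresholds(self.event_set.S)
        t = tuple(float(x) for x in self.severity_thresholds)
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("severity_thresholds must be strictly increasing")
        if t[0] < 0 or t[-1] > self.event_set.S:
            raise ValueError(f"severity_thresholds must lie within [0, {self.event_set.S}]")
        self.severity_thresholds = t
        if not 0.0 <= self.grade_flip_prob < 1.0:
            raise ValueError("grade_flip_prob must lie in [0, 1)")

    def _mean(self, name: str) -> float:
        if isinstance(self.control_mean, Mapping):
            return float(self.control_mean[name])
        return float(self.control_mean)

    def _sd(self, name: str) -> float:
        if isinstance(self.control_sd, Mapping):
            return float(self.control_sd[name])
        return float(self.control_sd)

    def fractions(self) -> np.ndarray:
        return np.array([s.fraction for s in self.subtypes])


def default_severity_thresholds(S: int) -> tuple[float, ...]:
    """Stage cutpoints yielding a grade distribution like a real KOA cohort.

    For S = 32 these are (1, 3, 14, 27): under a uniform stage prior the
    grade 0/1, 2, 3, 4 shares are roughly 9, 33, 39, and 18% — close to the
    7.5/34/41/18% reported for the 678-knee cohort the generator emulates.
    """
    if S < 4:
        raise ValueError("need S >= 4 for five severity grades")
    anchors = np.array([1.0, 3.0, 14.0, 27.0]) / 32.0 * S
    # every cutpoint at least 1 so stage 0 is always grade 0, and strictly
    # increasing after rounding on small S
    t = np.maximum(np.round(anchors), 1.0)
    for i in range(1, 4):
        t[i] = max(t[i], t[i - 1] + 1)
    return tuple(float(x) for x in t)


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth.

    ``raw_values`` is on the raw measurement scale (direction applied);
    ``z_values`` are the generator's direction-adjusted z-scores (expected
    trajectory at the true stage plus noise), which control-referenced
    z-scoring of ``raw_values`` recovers.
    """

    raw_values: pd.DataFrame
    z_values: pd.DataFrame
    demographics: pd.DataFrame
    severity_grade: np.ndarray
    truth_subtype: np.ndarray
    truth_stage: np.ndarray
    config: CohortConfig

    def __post_init__(self) -> None:
        S = self.config.event_set.S
        if self.raw_values.isna().any().any():
            raise ValueError("cohort table must have no missing values")
        if np.any((self.truth_stage < 0) | (self.truth_stage > S)):
            raise ValueError(f"truth_stage must lie in 0..{S}")


def generate_control_group(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Gaussian control-group table with the configured location and scale."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    cols = {}
    for name in config.event_set.biomarkers:
        cols[name] = rng.normal(
            config._mean(name), config._sd(name), size=config.n_controls
        )
    return pd.DataFrame(cols)


def severity_from_stage(
    stage: int,
    thresholds: Sequence[float],
    flip_prob: float = 0.0,
    rng: np.random.Generator | None = None,
) -> int:
    """Ordinal grade 0..len(thresholds) from a stage by threshold counting.

    Monotone non-decreasing in stage when ``flip_prob`` is 0; otherwise the
    grade moves to an adjacent grade with probability ``flip_prob``.
    """
    t = np.asarray(thresholds, dtype=float)
    if t.ndim != 1 or len(t) == 0 or np.any(np.diff(t) <= 0):
        raise ValueError("thresholds must be non-empty and strictly increasing")
    if stage < 0:
        raise ValueError("stage must be non-negative")
    grade = int(np.searchsorted(t, stage, side="right"))
    if flip_prob > 0.0:
        if rng is None:
            rng = np.random.default_rng()
        if rng.random() < flip_prob:
            step = 1 if rng.random() < 0.5 else -1
            grade = int(np.clip(grade + step, 0, len(t)))
    return grade


def generate_patient_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a cohort with known subtypes, stages, severity, and demographics.

    Deterministic given the config (including its seed): subtype ~
    categorical(fractions), stage ~ uniform{0..S}, z = trajectory(stage) +
    Normal(0, noise_sd), raw = control_mean + direction * z * control_sd.
    """
    es = config.event_set
    S = es.S
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = config.n_subjects
    c = len(config.subtypes)

    subtype = rng.choice(c, size=n, p=config.fractions())
    stage = rng.integers(0, S + 1, size=n)
    trajs = [
        expected_trajectory(np.asarray(s.sequence.order), es) for s in config.subtypes
    ]
    z_true = np.stack([trajs[subtype[j]][stage[j]] for j in range(n)])
    z = z_true + rng.normal(0.0, config.noise_sd, size=z_true.shape)

    # directions live on BiomarkerDefs; the event set itself is directionless
    direction = {name: 1.0 for name in es.biomarkers}
    if config.biomarker_defs:
        direction.update(
            {d.name: float(d.direction) for d in config.biomarker_defs}
        )

    raw = np.empty_like(z)
    for b, name in enumerate(es.biomarkers):
        raw[:, b] = config._mean(name) + direction.get(name, 1.0) * z[:, b] * config._sd(name)

    grade = np.array(
        [
            severity_from_stage(
                int(k), config.severity_thresholds, config.grade_flip_prob, rng
            )
            for k in stage
        ],
        dtype=int,
    )

    demo = config.demographics
    age_mu, age_sd = demo.get("age", DEFAULT_DEMOGRAPHICS["age"])
    bmi_mu, bmi_sd = demo.get("bmi", DEFAULT_DEMOGRAPHICS["bmi"])
    p_female = demo.get("gender", DEFAULT_DEMOGRAPHICS["gender"])
    p_injury = demo.get("injury", DEFAULT_DEMOGRAPHICS["injury"])
    age = rng.normal(age_mu, age_sd, size=n)
    bmi = rng.normal(bmi_mu, bmi_sd, size=n)
    gender = (rng.random(n) < p_female).astype(int)
    injury = (rng.random(n) < p_injury).astype(int)
    if config.subtype_demographic_shift:
        for t, shifts in config.subtype_demographic_shift.items():
            mask = subtype == t
            age[mask] += shifts.get("age", 0.0)
            bmi[mask] += shifts.get("bmi", 0.0)
    demographics = pd.DataFrame(
        {"age": age, "gender": gender, "bmi": bmi, "injury": injury}
    )

    cols = list(es.biomarkers)
    return SyntheticCohort(
        raw_values=pd.DataFrame(raw, columns=cols),
        z_values=pd.DataFrame(z, columns=cols),
        demographics=demographics,
        severity_grade=grade,
        truth_subtype=subtype.astype(int),
        truth_stage=stage.astype(int),
        config=config,
    )


def random_subtype_specs(
    event_set: EventSet,
    fractions: Sequence[float],
    seed: int = 0,
    min_tau_separation: float | None = 0.3,
    max_tries: int = 200,
    reversed_pair: bool = False,
    blocked: bool = False,
) -> list[SubtypeSpec]:
    """Draw distinct ground-truth sequences with the given fractions.

    With ``reversed_pair`` (two subtypes only), the subtypes progress
    biomarkers one at a time in opposite orders — the maximally separated
    two-subtype configuration.  With ``blocked``, every subtype is a block
    sequence over its own random biomarker order (archetypal subtypes with
    distinct lesion chronology), redrawn until pairwise separation holds.

    Sequences are drawn uniformly from the valid orderings; when
    ``min_tau_separation`` is not None, redraws until every pair of
    sequences has Kendall tau at most that value, giving well-separated
    subtypes.  (Within-biomarker z-order constraints are shared by all valid
    orderings, so pairwise tau has a positive floor; 0.3 is comfortably
    above it for typical event sets while still forcing strong disagreement
    on cross-biomarker ordering.)
    """
    from .events import sequence_kendall_tau

    rng = np.random.default_rng(seed)
    f = np.asarray(fractions, dtype=float)
    if abs(f.sum() - 1.0) > 1e-12:
        raise ValueError("fractions must sum to 1")
    if reversed_pair:
        if len(f) != 2:
            raise ValueError("reversed_pair requires exactly two subtypes")
        # block construction: each subtype progresses one biomarker fully
        # before the next, the two subtypes visiting biomarkers in opposite
        # orders — cross-biomarker event pairs are maximally discordant
        border = rng.permutation(event_set.n_biomarkers)
        per_bio = [
            np.flatnonzero(event_set.event_biomarker_idx == b)
            for b in range(event_set.n_biomarkers)
        ]
        first = np.concatenate([per_bio[b] for b in border])
        second = np.concatenate([per_bio[b] for b in border[::-1]])
        orders = [first, second]
        return [
            SubtypeSpec(
                sequence=EventSequence(
                    order=tuple(int(i) for i in o), event_set=event_set
                ),
                fraction=float(p),
            )
            for o, p in zip(orders, f)
        ]
    per_bio = [
        np.flatnonzero(event_set.event_biomarker_idx == b)
        for b in range(event_set.n_biomarkers)
    ]
    for _ in range(max_tries):
        if blocked:
            orders = [
                np.concatenate(
                    [per_bio[b] for b in rng.permutation(event_set.n_biomarkers)]
                )
                for _ in f
            ]
        else:
            orders = [random_valid_order(event_set, rng) for _ in f]
        if min_tau_separation is None or len(orders) == 1:
            break
        taus = [
            sequence_kendall_tau(orders[i], orders[j])
            for i in range(len(orders))
            for j in range(i + 1, len(orders))
        ]
        if max(taus) <= min_tau_separation:
            break
    else:
        raise RuntimeError("could not draw sufficiently separated sequences")
    return [
        SubtypeSpec(
            sequence=EventSequence(order=tuple(int(i) for i in o), event_set=event_set),
            fraction=float(p),
        )
        for o, p in zip(orders, f)
    ]
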