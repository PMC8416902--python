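"""Shared fixtures: small event sets, synthetic cohorts, enumeration oracles.

The oracle functions re-derive the model quantities by explicit enumeration
(itertools + scipy.stats.norm), independently of the package's vectorized
log-space implementation, so they can serve as ground truth on small
instances.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.stats import norm

from koaprog import (
    BiomarkerDef,
    CohortConfig,
    Event,
    EventSet,
    EventSequence,
    generate_patient_cohort,
    random_subtype_specs,
)


@pytest.fixture
def es3() -> EventSet:
    """S=3: biomarker A with events z=1,2 (max 3); B with z=1 (max 2)."""
    return EventSet(
        events=(Event("A", 1.0), Event("A", 2.0), Event("B", 1.0)),
        max_z={"A": 3.0, "B": 2.0},
    )


@pytest.fixture
def es4() -> EventSet:
    """S=4: two biomarkers with events z=1,2 each."""
    return EventSet(
        events=(Event("A", 1.0), Event("A", 2.0), Event("B", 1.0), Event("B", 2.0)),
        max_z={"A": 3.0, "B": 3.0},
    )


@pytest.fixture
def es6() -> EventSet:
    """S=6: A(1,2,3), B(1), C(1,2)."""
    return EventSet(
        events=(
            Event("A", 1.0),
            Event("A", 2.0),
            Event("A", 3.0),
            Event("B", 1.0),
            Event("C", 1.0),
            Event("C", 2.0),
        ),
        max_z={"A": 5.0, "B": 2.0, "C": 3.0},
    )


def make_sim_event_set(n_biomarkers: int = 5) -> EventSet:
    """S = 2 * n_biomarkers: each biomarker has events z=1 and z=2."""
    events = []
    max_z = {}
    for i in range(n_biomarkers):
        name = f"bm{i}"
        events += [Event(name, 1.0), Event(name, 2.0)]
        max_z[name] = 3.0
    return EventSet(events=tuple(events), max_z=max_z)


@pytest.fixture
def es10() -> EventSet:
    return make_sim_event_set(5)


def make_cohort(
    event_set: EventSet,
    fractions=(0.5, 0.5),
    n: int = 600,
    noise_sd: float = 1.0,
    seed: int = 0,
    grade_flip_prob: float = 0.0,
    defs: list[BiomarkerDef] | None = None,
    reversed_pair: bool = False,
    blocked: bool = False,
    **kwargs,
):
    """Well-separated synthetic cohort with ground truth."""
    specs = random_subtype_specs(
        event_set, fractions, seed=seed, reversed_pair=reversed_pair, blocked=blocked
    )
    cfg = CohortConfig(
        event_set=event_set,
        subtypes=specs,
        biomarker_defs=defs,
        n_subjects=n,
        noise_sd=noise_sd,
        grade_flip_prob=grade_flip_prob,
        seed=seed,
        **kwargs,
    )
    return generate_patient_cohort(cfg)


# ---------------------------------------------------------------------------
# Enumeration oracles (independent of koaprog.likelihood)


def oracle_trajectory_value(order, es: EventSet, biomarker: str, stage: int) -> float:
    """Expected z of one biomarker at one stage, by explicit knot walking."""
    order = list(order)
    knots = [(0.0, 0.0)]
    for p, ev in enumerate(order, start=1):
        e = es.events[ev]
        if e.biomarker == biomarker:
            knots.append((float(p), float(e.z)))
    if knots[-1][0] < es.S:
        knots.append((float(es.S), float(es.max_z[biomarker])))
    x = float(stage)
    for (x0, y0), (x1, y1) in zip(knots, knots[1:]):
        if x0 <= x <= x1:
            if x1 == x0:
                return y1
            return y0 + (y1 - y0) * (x - x0) / (x1 - x0)
    return knots[-1][1]


def oracle_stage_density(x, order, es: EventSet, stage: int, sigma=1.0) -> float:
    """Density of one subject at one stage: product of per-biomarker normals."""
    sig = np.broadcast_to(np.asarray(sigma, float), (es.n_biomarkers,))
    dens = 1.0
    for b, name in enumerate(es.biomarkers):
        mu = oracle_trajectory_value(order, es, name, stage)
        dens *= norm.pdf(x[b], loc=mu, scale=sig[b])
    return dens


def oracle_marginal_lik(x, order, es: EventSet, sigma=1.0) -> float:
    """(1 / (S+1)) * sum over stages of the per-stage density."""
    return float(
        np.mean([oracle_stage_density(x, order, es, k, sigma) for k in range(es.S + 1)])
    )


def oracle_stage_posterior(x, order, es: EventSet, sigma=1.0) -> np.ndarray:
    dens = np.array(
        [oracle_stage_density(x, order, es, k, sigma) for k in range(es.S + 1)]
    )
    return dens / dens.sum()


def oracle_dataset_loglik(X, orders, fractions, es: EventSet, sigma=1.0) -> float:
    total = 0.0
    for x in np.atleast_2d(X):
        lik = sum(
            f * oracle_marginal_lik(x, o, es, sigma)
            for f, o in zip(fractions, orders)
        )
        total += np.log(lik)
    return float(total)


def valid_orders(es: EventSet) -> list[tuple[int, ...]]:
    """All valid event orderings of a (small) event set, by filtering."""
    out = []
    for perm in itertools.permutations(range(es.S)):
        pos = {ev: p for p, ev in enumerate(perm)}
        ok = True
        for b in range(es.n_biomarkers):
            evs = [i for i in range(es.S) if es.event_biomarker_idx[i] == b]
            if any(pos[e1] >= pos[e2] for e1, e2 in zip(evs, evs[1:])):
                ok = False
                break
        if ok:
            out.append(perm)
    return out
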