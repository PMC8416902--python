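"""Linear z-score event model: trajectories and stage-marginal likelihoods.

Under one event sequence, each biomarker's expected z-score is a piecewise
linear function of the discrete stage: it starts at 0 at stage 0, passes
through its event thresholds at the sequence positions where those events
occur, and reaches the biomarker's maximum z-score at the final stage S.
Observed z-scores are modelled as Gaussian around the stage's expected value
with a per-biomarker noise scale (default 1, appropriate for
control-referenced z-scores).  Subjects are assigned a discrete uniform
prior over the S+1 stages; all accumulation is in log space.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .events import EventSet, EventSequence, validate_order

_LOG2PI = float(np.log(2.0 * np.pi))


def as_matrix(X, event_set: EventSet) -> np.ndarray:
    """Coerce a z-score table to an (n, n_biomarkers) float array.

    DataFrames are reindexed to the event set's biomarker order; arrays must
    already have one column per biomarker.
    """
    if isinstance(X, pd.DataFrame):
        missing = [b for b in event_set.biomarkers if b not in X.columns]
        if missing:
            raise ValueError(f"z-score table is missing biomarker columns {missing}")
        X = X.loc[:, list(event_set.biomarkers)].to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != event_set.n_biomarkers:
        raise ValueError(
            f"expected {event_set.n_biomarkers} biomarker columns, got {X.shape[1]}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("z-score table contains non-finite values")
    return X


def _order_array(seq, event_set: EventSet) -> np.ndarray:
    if isinstance(seq, EventSequence):
        return np.asarray(seq.order, dtype=np.intp)
    return validate_order(seq, event_set)


def _sigma_array(sigma, event_set: EventSet) -> np.ndarray:
    s = np.broadcast_to(np.asarray(sigma, dtype=float), (event_set.n_biomarkers,))
    if np.any(s <= 0):
        raise ValueError("sigma must be positive")
    return s


def _trajectory_unchecked(order: np.ndarray, event_set: EventSet) -> np.ndarray:
    """Trajectory matrix for a known-valid order (hot path, no validation)."""
    S = event_set.S
    pos = np.empty(S, dtype=np.intp)
    pos[order] = np.arange(1, S + 1)
    stages = np.arange(S + 1, dtype=float)
    traj = np.empty((S + 1, event_set.n_biomarkers), dtype=float)
    for b, name in enumerate(event_set.biomarkers):
        evs = np.flatnonzero(event_set.event_biomarker_idx == b)
        xs = [0.0] + [float(pos[e]) for e in evs]
        ys = [0.0] + [float(event_set.event_z[e]) for e in evs]
        if xs[-1] < S:
            xs.append(float(S))
            ys.append(float(event_set.max_z[name]))
        traj[:, b] = np.interp(stages, xs, ys)
    return traj


def expected_trajectory(seq, event_set: EventSet) -> np.ndarray:
    """Expected z-score of every biomarker at every stage.

    For a biomarker with events z1 < ... < zm at sequence positions
    p1 < ... < pm, the trajectory linearly interpolates the knots
    (0, 0), (p1, z1), ..., (pm, zm), (S, max_z); the final knot is dropped
    when pm = S.  Evaluated at the integer stages 0..S.

    Returns
    -------
    ndarray of shape (S + 1, n_biomarkers)
    """
    order = _order_array(seq, event_set)
    return _trajectory_unchecked(order, event_set)


def stage_logliks(X, traj: np.ndarray, sigma, event_set: EventSet) -> np.ndarray:
    """Log density of each subject at each stage: shape (n, S + 1)."""
    X = as_matrix(X, event_set)
    s = _sigma_array(sigma, event_set)
    const = -0.5 * event_set.n_biomarkers * _LOG2PI - float(np.sum(np.log(s)))
    resid = (X[:, None, :] - traj[None, :, :]) / s
    return const - 0.5 * np.einsum("nkb,nkb->nk", resid, resid)


def subject_loglik_at_stage(x, seq, stage: int, sigma=1.0, *, event_set=None) -> float:
    """Log density of one subject's z-scores at a fixed stage."""
    es = event_set if event_set is not None else seq.event_set
    if not 0 <= int(stage) <= es.S:
        raise ValueError(f"stage must lie in 0..{es.S}")
    traj = expected_trajectory(seq, es)
    ll = stage_logliks(np.atleast_2d(x), traj, sigma, es)
    return float(ll[0, int(stage)])


def subject_log_marginal(X, seq, sigma=1.0, *, event_set=None) -> np.ndarray:
    """Per-subject log likelihood marginalized over the uniform stage prior.

    log [ (1 / (S+1)) * sum_k p(x | stage k) ], computed with log-sum-exp.
    """
    es = event_set if event_set is not None else seq.event_set
    traj = expected_trajectory(seq, es)
    ll = stage_logliks(X, traj, sigma, es)
    return logsumexp(ll, axis=1) - np.log(es.S + 1)


def subject_marginal_lik(x, seq, sigma=1.0, *, event_set=None) -> float:
    """Stage-marginalized likelihood of a single subject (natural scale)."""
    return float(np.exp(subject_log_marginal(np.atleast_2d(x), seq, sigma, event_set=event_set)[0]))


def stage_posterior(x, seq, sigma=1.0, *, event_set=None) -> np.ndarray:
    """Posterior over stages 0..S for one subject under a uniform stage prior."""
    es = event_set if event_set is not None else seq.event_set
    traj = expected_trajectory(seq, es)
    ll = stage_logliks(np.atleast_2d(x), traj, sigma, es)[0]
    post = np.exp(ll - logsumexp(ll))
    return post / post.sum()


def stage_posteriors(X, seq, sigma=1.0, *, event_set=None) -> np.ndarray:
    """Row-normalized stage posteriors for a whole table: shape (n, S + 1)."""
    es = event_set if event_set is not None else seq.event_set
    traj = expected_trajectory(seq, es)
    ll = stage_logliks(X, traj, sigma, es)
    post = np.exp(ll - logsumexp(ll, axis=1, keepdims=True))
    return post / post.sum(axis=1, keepdims=True)


def mixture_log_marginals(
    X, seqs: Sequence, sigma, event_set: EventSet
) -> np.ndarray:
    """Per-subject, per-subtype stage-marginal log likelihoods: (n, c)."""
    cols = [subject_log_marginal(X, s, sigma, event_set=event_set) for s in seqs]
    return np.stack(cols, axis=1)


def dataset_loglik(
    X,
    seqs: Sequence,
    fractions: Sequence[float],
    sigma=1.0,
    *,
    event_set: EventSet | None = None,
) -> float:
    """Total log likelihood of the data under a mixture of sequences.

    sum_j log sum_c f_c * P(x_j | sequence_c), the quantity maximized by the
    subtype-progression fit.
    """
    es = event_set
    if es is None:
        first = seqs[0]
        if not isinstance(first, EventSequence):
            raise ValueError("event_set is required when sequences are plain orders")
        es = first.event_set
    f = np.asarray(fractions, dtype=float)
    if f.ndim != 1 or len(f) != len(seqs):
        raise ValueError("fractions must be one per sequence")
    if abs(f.sum() - 1.0) > 1e-9 or np.any(f < 0):
        raise ValueError("fractions must be non-negative and sum to 1")
    Xm = as_matrix(X, es)
    if Xm.shape[0] == 0:
        raise ValueError("dataset is empty")
    logm = mixture_log_marginals(Xm, seqs, sigma, es)
    with np.errstate(divide="ignore"):
        return float(np.sum(logsumexp(logm + np.log(f), axis=1)))
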