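"""Fitting the mixture of linear z-score progression models.

The model has ``c`` subtypes, each a full ordering of the z-score events,
mixing fractions ``f``, and a Gaussian noise scale per biomarker.  Fitting
alternates:

* greedy coordinate ascent over orderings — repeatedly remove one event and
  reinsert it at the (weighted) log-likelihood-maximizing valid position;
* EM over the mixture — responsibilities from the stage-marginal subject
  likelihoods, fractions from mean responsibilities;
* hierarchical growth — the (c+1)-subtype model is seeded by splitting one
  subtype of the c-subtype model into two random halves and polishing with
  EM.

Sequence uncertainty is summarized by Metropolis-Hastings sampling over
orderings (propose relocating one event to a uniformly chosen valid
position), reported as an event x position frequency matrix (the positional
variance diagram).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .events import (
    EventSequence,
    EventSet,
    random_valid_order,
    validate_order,
)
from .likelihood import (
    as_matrix,
    _sigma_array,
    _trajectory_unchecked,
)

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))
_TIE_EPS = 1e-12  # strict-improvement margin in greedy reinsertion


def _log_marginal_unchecked(X, order, sigma_arr, es) -> np.ndarray:
    """Per-subject stage-marginal log likelihood (validated inputs only)."""
    traj = _trajectory_unchecked(np.asarray(order, dtype=np.intp), es)
    const = -0.5 * es.n_biomarkers * _LOG2PI - float(np.sum(np.log(sigma_arr)))
    r = (X[:, None, :] - traj[None, :, :]) / sigma_arr
    ll = const - 0.5 * np.einsum("nkb,nkb->nk", r, r)
    return logsumexp(ll, axis=1) - np.log(es.S + 1)


def _score_batch(X, cands, w, sigma_arr, es) -> np.ndarray:
    """Weighted stage-marginal log likelihood of several candidate orders.

    ``cands`` is an (m, S) array of known-valid orders; returns m scores.
    One broadcasted residual evaluation covers all candidates at once — the
    inner loop of the greedy ascent.
    """
    trajs = np.stack([_trajectory_unchecked(o, es) for o in cands])
    const = -0.5 * es.n_biomarkers * _LOG2PI - float(np.sum(np.log(sigma_arr)))
    r = (X[None, :, None, :] - trajs[:, None, :, :]) / sigma_arr
    ll = const - 0.5 * np.einsum("mnkb,mnkb->mnk", r, r)
    marg = logsumexp(ll, axis=2) - np.log(es.S + 1)
    return marg @ w


def _weighted_score(X, order, w, sigma, es) -> float:
    """Weighted stage-marginal log likelihood of one ordering."""
    sigma_arr = _sigma_array(sigma, es)
    return float(w @ _log_marginal_unchecked(X, np.asarray(order, np.intp), sigma_arr, es))


def _insertion_bounds(base: np.ndarray, event: int, es: EventSet) -> tuple[int, int]:
    """Valid insertion index range [lo, hi] for ``event`` into ``base``."""
    b = es.event_biomarker_idx[event]
    z = es.event_z[event]
    lo, hi = 0, len(base)
    for j, e in enumerate(base):
        if es.event_biomarker_idx[e] == b:
            if es.event_z[e] < z:
                lo = j + 1
            elif es.event_z[e] > z:
                hi = min(hi, j)
                break
    return lo, hi


def _greedy_optimize(
    X: np.ndarray,
    es: EventSet,
    w: np.ndarray,
    order: np.ndarray,
    sigma,
    max_sweeps: int = 60,
) -> tuple[np.ndarray, float]:
    order = np.array(order, dtype=np.intp)
    sigma_arr = _sigma_array(sigma, es)
    best = float(w @ _log_marginal_unchecked(X, order, sigma_arr, es))
    for _ in range(max_sweeps):
        improved = False
        for ev in range(es.S):
            cur = int(np.flatnonzero(order == ev)[0])
            base = np.delete(order, cur)
            lo, hi = _insertion_bounds(base, ev, es)
            slots = [p for p in range(lo, hi + 1) if p != cur]
            if not slots:
                continue
            cands = np.stack([np.insert(base, p, ev) for p in slots])
            scores = _score_batch(X, cands, w, sigma_arr, es)
            k = int(np.argmax(scores))  # argmax takes the first (lowest slot) on ties
            if scores[k] > best + _TIE_EPS:
                best = float(scores[k])
                order = cands[k]
                improved = True
        if not improved:
            break
    return order, best


def optimize_sequence(
    X,
    init: EventSequence,
    weights=None,
    sigma: float | np.ndarray = 1.0,
) -> EventSequence:
    """Greedy coordinate ascent over event orderings.

    Repeatedly removes one event and reinserts it at the position maximizing
    the weighted stage-marginal log likelihood, sweeping all events until a
    full sweep makes no change.  The returned sequence's weighted log
    likelihood is never below the initial one; exact ties resolve to the
    lowest position.
    """
    es = init.event_set
    Xm = as_matrix(X, es)
    if weights is None:
        w = np.ones(Xm.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (Xm.shape[0],) or np.any(w < 0):
            raise ValueError("weights must be a non-negative vector, one per subject")
        if w.sum() <= 0:
            raise ValueError("degenerate responsibility: weights sum to zero")
    order, _ = _greedy_optimize(Xm, es, w, np.asarray(init.order), sigma)
    return EventSequence(order=tuple(int(i) for i in order), event_set=es)


@dataclass
class SequencePosterior:
    """MCMC posterior over event orderings, one chain per subtype.

    Attributes
    ----------
    samples
        Per subtype, an (n_samples, S) integer array of post-burn-in
        orderings.
    positional_variance
        Per subtype, an (S, S) event x position frequency matrix (rows are
        events in event-set order, columns positions 1..S; rows sum to 1).
        The textual analog of the positional variance diagram.
    acceptance_rate
        Per-subtype Metropolis-Hastings acceptance rate.
    ml_orders
        Per subtype, the highest-likelihood sampled ordering.
    """

    samples: list[np.ndarray]
    positional_variance: list[np.ndarray]
    acceptance_rate: list[float]
    ml_orders: list[np.ndarray] = field(default_factory=list)


class SubtypeProgressionModel(BaseEstimator):
    """Mixture of linear z-score event progression models.

    An unsupervised estimator over a subjects x biomarkers z-score table.
    ``fit`` recovers, for each of ``n_subtypes`` subtypes, a full ordering of
    the z-score events (the subtype's progression sequence) together with
    mixing fractions; ``predict`` returns each subject's most probable
    subtype and ``predict_proba`` the subtype posterior.  Stage posteriors
    are available through :mod:`koaprog.assignment`.

    Parameters
    ----------
    event_set : EventSet
        The retained z-score events (defines the stage axis).
    n_subtypes : int, default=1
        Number of mixture components c.
    sigma : float or array, default=1.0
        Gaussian noise scale per biomarker on the z scale.
    n_starts : int, default=25
        Random restarts of the greedy ascent for the single-subtype fit.
    split_starts : int, default=2
        Random half-splits tried per subtype when growing from c to c+1
        (plus as many append-random and full-restart seeds).
    polish_top : int, default=2
        Number of best-scoring exploratory candidates polished to full
        tolerance at each growth step.
    max_iter : int, default=100
        Maximum EM iterations per subtype count.
    tol : float, default=1e-6
        Absolute log-likelihood EM convergence tolerance.
    random_state : int or None
        Seed for restarts and splits.

    Attributes
    ----------
    sequences_ : list of EventSequence
        Fitted subtype progression sequences.
    fractions_ : ndarray of shape (n_subtypes,)
        Fitted mixing fractions (sum to 1).
    loglik_ : float
        Dataset log likelihood at the fitted parameters.
    em_traces_ : dict mapping c -> list of float
        Per-iteration log-likelihood traces (non-decreasing) for each
        subtype count visited while growing the model.
    converged_ : bool
        Whether the final EM loop reached ``tol`` within ``max_iter``.
    """

    def __init__(
        self,
        event_set: EventSet | None = None,
        n_subtypes: int = 1,
        sigma: float = 1.0,
        n_starts: int = 25,
        split_starts: int = 2,
        polish_top: int = 2,
        max_iter: int = 100,
        tol: float = 1e-6,
        random_state: int | None = None,
    ):
        self.event_set = event_set
        self.n_subtypes = n_subtypes
        self.sigma = sigma
        self.n_starts = n_starts
        self.split_starts = split_starts
        self.polish_top = polish_top
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # -- internal helpers --------------------------------------------------

    def _es(self) -> EventSet:
        if self.event_set is None:
            raise ValueError("event_set must be provided")
        return self.event_set

    def _log_marginals(self, Xm: np.ndarray, orders) -> np.ndarray:
        es = self._es()
        sigma_arr = _sigma_array(self.sigma, es)
        return np.stack(
            [
                _log_marginal_unchecked(Xm, np.asarray(o, np.intp), sigma_arr, es)
                for o in orders
            ],
            axis=1,
        )

    def _em(self, Xm, orders, fractions, rng, tol=None, max_iter=None):
        """Alternating EM; returns orders, fractions, loglik, trace, converged.

        Each outer iteration runs the cheap fraction/responsibility EM cycle
        to convergence with the sequences fixed, then one greedy sequence
        update per subtype under the latest responsibilities.  Both steps
        increase the observed-data log likelihood, so the trace is monotone
        (asserted).
        """
        es = self._es()
        tol = self.tol if tol is None else tol
        max_iter = self.max_iter if max_iter is None else max_iter
        orders = [np.array(o, dtype=np.intp) for o in orders]
        f = np.asarray(fractions, dtype=float)
        trace: list[float] = []
        converged = False
        ll = -np.inf
        for _ in range(max_iter):
            prev_outer = ll
            logm = self._log_marginals(Xm, orders)
            for _inner in range(100):
                lw = logm + np.log(f)
                per_subject = logsumexp(lw, axis=1)
                ll = float(per_subject.sum())
                if trace and ll < trace[-1] - 1e-6:
                    raise AssertionError(
                        f"EM log likelihood decreased: {trace[-1]} -> {ll}"
                    )
                trace.append(ll)
                resp = np.exp(lw - per_subject[:, None])
                f_new = np.clip(resp.mean(axis=0), 1e-12, None)
                f_new = f_new / f_new.sum()
                if np.max(np.abs(f_new - f)) < 1e-9:
                    f = f_new
                    break
                f = f_new
            changed = False
            for t in range(len(orders)):
                new_order, _ = _greedy_optimize(
                    Xm, es, resp[:, t], orders[t], self.sigma
                )
                if not np.array_equal(new_order, orders[t]):
                    changed = True
                orders[t] = new_order
            if not changed:
                converged = True
                break
            if ll - prev_outer < tol:
                converged = True
                break
        # final likelihood at the returned parameters (sequences may have
        # been updated after the last trace entry)
        logm = self._log_marginals(Xm, orders)
        ll = float(logsumexp(logm + np.log(f), axis=1).sum())
        if trace and ll > trace[-1]:
            trace.append(ll)
        return orders, f, ll, trace, converged

    def _fit_single(self, Xm, rng) -> tuple[np.ndarray, float]:
        es = self._es()
        w = np.ones(Xm.shape[0])
        best_order, best_score = None, -np.inf
        for _ in range(max(1, self.n_starts)):
            init = random_valid_order(es, rng)
            order, score = _greedy_optimize(Xm, es, w, init, self.sigma)
            if score > best_score:
                best_order, best_score = order, score
        return best_order, best_score

    def _split_candidates(self, Xm, orders, fractions, rng):
        """Candidate (orders, fractions) seeds with one extra subtype.

        Three families: duplicate one subtype (exactly reproduces the parent
        likelihood, so growing can never fit worse); split one subtype's
        hard-assigned subjects into random halves and greedily refit each
        half; and append a freshly drawn random sequence.  The caller EM-
        polishes every candidate and keeps the best.
        """
        es = self._es()
        logm = self._log_marginals(Xm, orders)
        lw = logm + np.log(fractions)
        resp = np.exp(lw - logsumexp(lw, axis=1, keepdims=True))
        hard = resp.argmax(axis=1)
        candidates = []
        c = len(orders)
        sigma_arr = _sigma_array(self.sigma, es)
        for _ in range(max(1, self.split_starts)):
            # append a fresh random sequence to the parent
            rnd_orders = [o.copy() for o in orders] + [random_valid_order(es, rng)]
            rnd_f = np.append(fractions * c / (c + 1.0), 1.0 / (c + 1.0))
            candidates.append((rnd_orders, rnd_f / rnd_f.sum()))
            # full restart: all sequences random, uniform fractions — escapes
            # the parent's compromise sequence entirely
            full = [random_valid_order(es, rng) for _ in range(c + 1)]
            candidates.append((full, np.full(c + 1, 1.0 / (c + 1))))
        # worst-fit seed: subjects the current mixture explains poorly often
        # ARE the missing subtype; fit the new sequence on the bottom fifth
        per_subject = logsumexp(lw, axis=1)
        n_tail = max(2, len(per_subject) // 5)
        tail = np.argsort(per_subject)[:n_tail]
        for init in [orders[int(np.argmax(fractions))], random_valid_order(es, rng)]:
            o_new, _ = _greedy_optimize(
                Xm[tail], es, np.ones(n_tail), init, self.sigma
            )
            wf_orders = [o.copy() for o in orders] + [o_new]
            wf_f = np.append(
                fractions * (1.0 - n_tail / len(per_subject)),
                n_tail / len(per_subject),
            )
            candidates.append((wf_orders, wf_f / wf_f.sum()))
        for t in range(len(orders)):
            idx = np.flatnonzero(hard == t)
            # duplication seed: exactly reproduces the parent likelihood
            dup_orders = [o.copy() for o in orders] + [orders[t].copy()]
            dup_f = np.append(fractions.copy(), fractions[t] / 2.0)
            dup_f[t] /= 2.0
            candidates.append((dup_orders, dup_f / dup_f.sum()))
            if len(idx) < 2:
                logger.info(
                    "subtype %d has %d assigned subject(s); random-half split skipped",
                    t,
                    len(idx),
                )
                continue
            for _ in range(max(1, self.split_starts)):
                perm = rng.permutation(idx)
                halves = (perm[: len(perm) // 2], perm[len(perm) // 2 :])
                new_orders = []
                for h in halves:
                    # refit each half from the parent sequence and from random
                    # restarts: the parent is a compromise between the split
                    # halves, and greedy ascent seeded only there tends to
                    # stay at it
                    inits = [orders[t]] + [
                        random_valid_order(es, rng) for _ in range(2)
                    ]
                    cand_best = None
                    for init in inits:
                        o, sc = _greedy_optimize(
                            Xm[h], es, np.ones(len(h)), init, self.sigma
                        )
                        if cand_best is None or sc > cand_best[1]:
                            cand_best = (o, sc)
                    new_orders.append(cand_best[0])
                cand_orders = [o.copy() for i, o in enumerate(orders) if i != t]
                cand_orders += new_orders
                cand_f = np.array(
                    [fractions[i] for i in range(len(orders)) if i != t]
                    + [
                        fractions[t] * len(halves[0]) / len(idx),
                        fractions[t] * len(halves[1]) / len(idx),
                    ]
                )
                candidates.append((cand_orders, cand_f / cand_f.sum()))
        return candidates

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y=None) -> "SubtypeProgressionModel":
        """Fit sequences and fractions by hierarchical greedy EM."""
        es = self._es()
        _sigma_array(self.sigma, es)
        Xm = as_matrix(X, es)
        n = Xm.shape[0]
        c_target = int(self.n_subtypes)
        if c_target < 1:
            raise ValueError("n_subtypes must be >= 1")
        if n < c_target:
            raise ValueError(f"need at least n_subtypes={c_target} subjects, got {n}")
        rng = np.random.default_rng(self.random_state)

        self.em_traces_ = {}
        order, _ = self._fit_single(Xm, rng)
        orders = [order]
        f = np.array([1.0])
        orders, f, ll, trace, conv = self._em(Xm, orders, f, rng)
        self.em_traces_[1] = trace
        explore_tol = max(self.tol, 1e-3)
        for c in range(2, c_target + 1):
            # cheap exploratory EM over every candidate seed, then a full-
            # tolerance polish of the winner
            explored = [
                self._em(
                    Xm,
                    cand_orders,
                    cand_f,
                    rng,
                    tol=explore_tol,
                    max_iter=min(30, self.max_iter),
                )
                for cand_orders, cand_f in self._split_candidates(Xm, orders, f, rng)
            ]
            explored.sort(key=lambda out: out[2], reverse=True)
            best = None
            for cand in explored[: max(1, self.polish_top)]:
                out = self._em(Xm, cand[0], cand[1], rng)
                if best is None or out[2] > best[2]:
                    best = (*out[:4], out[4], cand[3])
            orders, f, ll, trace, conv = best[:5]
            self.em_traces_[c] = best[5] + trace
        if not conv:
            logger.warning(
                "EM did not converge within max_iter=%d; best model returned",
                self.max_iter,
            )
        self.sequences_ = [
            EventSequence(order=tuple(int(i) for i in o), event_set=es) for o in orders
        ]
        self.fractions_ = f
        self.loglik_ = ll
        self.converged_ = conv
        self.n_features_in_ = es.n_biomarkers
        return self

    def log_marginals(self, X) -> np.ndarray:
        """Per-subject, per-subtype stage-marginal log likelihoods."""
        self._check_fitted()
        Xm = as_matrix(X, self._es())
        return self._log_marginals(Xm, [np.asarray(s.order) for s in self.sequences_])

    def predict_proba(self, X) -> np.ndarray:
        """Posterior subtype membership probabilities, shape (n, c)."""
        lw = self.log_marginals(X) + np.log(self.fractions_)
        p = np.exp(lw - logsumexp(lw, axis=1, keepdims=True))
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        """Most probable subtype index per subject."""
        return self.predict_proba(X).argmax(axis=1)

    def dataset_loglik(self, X) -> float:
        """Mixture log likelihood of a z-score table under the fitted model."""
        lw = self.log_marginals(X) + np.log(self.fractions_)
        return float(logsumexp(lw, axis=1).sum())

    def score(self, X, y=None) -> float:
        """Mean per-subject log likelihood (sklearn scoring convention)."""
        Xm = as_matrix(X, self._es())
        return self.dataset_loglik(Xm) / Xm.shape[0]

    def _check_fitted(self) -> None:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "sequences_")


def fit_progression(
    Z,
    event_set: EventSet,
    c: int,
    n_starts: int = 25,
    seed: int | None = None,
    **kwargs,
) -> SubtypeProgressionModel:
    """Thin functional wrapper over :class:`SubtypeProgressionModel`."""
    return SubtypeProgressionModel(
        event_set=event_set,
        n_subtypes=c,
        n_starts=n_starts,
        random_state=seed,
        **kwargs,
    ).fit(Z)


def split_and_fit(Z, model: SubtypeProgressionModel) -> SubtypeProgressionModel:
    """Grow a fitted c-subtype model to c+1 subtypes.

    Each existing subtype is tentatively split: its hard-assigned subjects
    are partitioned into two random halves and each half is greedily refit
    (a duplicate-the-subtype seed is also tried, which guarantees the grown
    model never fits worse than its parent).  The candidate with the highest
    full-data likelihood after EM polishing is kept.
    """
    model._check_fitted()
    grown = SubtypeProgressionModel(**model.get_params())
    grown.n_subtypes = len(model.sequences_) + 1
    es = model._es()
    Xm = as_matrix(Z, es)
    rng = np.random.default_rng(model.random_state)
    orders = [np.asarray(s.order, dtype=np.intp) for s in model.sequences_]
    explore_tol = max(grown.tol, 1e-3)
    explored = [
        grown._em(Xm, cand_orders, cand_f, rng, tol=explore_tol, max_iter=30)
        for cand_orders, cand_f in grown._split_candidates(
            Xm, orders, np.asarray(model.fractions_), rng
        )
    ]
    explored.sort(key=lambda out: out[2], reverse=True)
    best = None
    for cand in explored[: max(1, grown.polish_top)]:
        out = grown._em(Xm, cand[0], cand[1], rng)
        if best is None or out[2] > best[2]:
            best = (*out, cand[3])
    orders, f, ll, trace, conv = best[:5]
    trace = best[5] + trace
    grown.sequences_ = [
        EventSequence(order=tuple(int(i) for i in o), event_set=es) for o in orders
    ]
    grown.fractions_ = f
    grown.loglik_ = ll
    grown.converged_ = conv
    grown.em_traces_ = {grown.n_subtypes: trace}
    grown.n_features_in_ = es.n_biomarkers
    return grown


def mcmc_posterior(
    Z,
    model: SubtypeProgressionModel,
    n_iter: int = 10_000,
    burn_in: int = 1_000,
    seed: int | None = None,
) -> SequencePosterior:
    """Metropolis-Hastings posterior over each subtype's event ordering.

    One chain per subtype: a uniformly chosen event is proposed to relocate
    to a uniformly chosen position; proposals that would violate the
    within-biomarker z order are rejected before evaluation, otherwise the
    move is accepted with the mixture-likelihood ratio (the other subtypes'
    sequences and all fractions held fixed at their fitted values).
    """
    model._check_fitted()
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    es = model._es()
    Xm = as_matrix(Z, es)
    rng = np.random.default_rng(seed)
    S = es.S
    c = len(model.sequences_)
    sigma_arr = _sigma_array(model.sigma, es)
    logf = np.log(np.asarray(model.fractions_, dtype=float))
    base_logm = model.log_marginals(Xm) if Xm.shape[0] else np.zeros((0, c))

    samples: list[np.ndarray] = []
    pvds: list[np.ndarray] = []
    rates: list[float] = []
    ml_orders: list[np.ndarray] = []
    for t in range(c):
        order = np.asarray(model.sequences_[t].order, dtype=np.intp)

        def chain_ll(o: np.ndarray) -> float:
            if Xm.shape[0] == 0:
                return 0.0
            m = _log_marginal_unchecked(Xm, o, sigma_arr, es)
            logm = base_logm.copy()
            logm[:, t] = m
            return float(logsumexp(logm + logf, axis=1).sum())

        cur_ll = chain_ll(order)
        kept = np.empty((n_iter - burn_in, S), dtype=np.intp)
        accepted = 0
        best_ll, best_order = cur_ll, order.copy()
        for it in range(n_iter):
            ev = int(rng.integers(S))
            p = int(rng.integers(S))
            cur_pos = int(np.flatnonzero(order == ev)[0])
            base = np.delete(order, cur_pos)
            lo, hi = _insertion_bounds(base, ev, es)
            # inserting at slot p of the reduced sequence puts the event at
            # full-sequence position p; the proposal is symmetric in (ev, p)
            slot = p
            if lo <= slot <= hi:
                cand = np.insert(base, slot, ev)
                if not np.array_equal(cand, order):
                    cand_ll = chain_ll(cand)
                    if np.log(rng.random()) < cand_ll - cur_ll:
                        order, cur_ll = cand, cand_ll
                        accepted += 1
                        if cur_ll > best_ll:
                            best_ll, best_order = cur_ll, order.copy()
            if it >= burn_in:
                kept[it - burn_in] = order
        pvd = np.zeros((S, S))
        for row in kept:
            pvd[row, np.arange(S)] += 1.0
        pvd /= kept.shape[0]
        samples.append(kept)
        pvds.append(pvd)
        rates.append(accepted / n_iter)
        ml_orders.append(best_order)
    return SequencePosterior(
        samples=samples,
        positional_variance=pvds,
        acceptance_rate=rates,
        ml_orders=ml_orders,
    )
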