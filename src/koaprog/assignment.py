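"""Per-subject subtype and stage posteriors, and group-level summaries.

Given a fitted progression model, each subject receives a posterior over
subtypes (proportional to fraction x stage-marginal likelihood) and, within
each subtype, a posterior over stages 0..S.  A subject is *strongly
assigned* when its maximum subtype probability is at least 1.5 times each
other subtype's probability.  Group-level summaries (stage distribution and
strong-assignment rate by severity grade) mirror the standard evaluation of
staging consistency against an ordinal severity grade.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .inference import SubtypeProgressionModel
from .likelihood import as_matrix, stage_posteriors

logger = logging.getLogger(__name__)


@dataclass
class SubjectPosterior:
    """One subject's posterior over subtypes and stages.

    Attributes
    ----------
    subtype_probs
        Length-c vector, sums to 1.
    stage_probs
        (c, S+1) matrix of per-subtype stage posteriors; each row sums to 1.
    stage_marginal
        Subtype-marginalized stage posterior, length S+1.
    ml_subtype, ml_stage
        Argmaxes of ``subtype_probs`` and ``stage_marginal`` (ties resolve
        to the lower index / earlier stage).
    """

    subtype_probs: np.ndarray
    stage_probs: np.ndarray
    stage_marginal: np.ndarray
    ml_subtype: int
    ml_stage: int

    def __post_init__(self) -> None:
        if abs(self.subtype_probs.sum() - 1.0) > 1e-9:
            raise ValueError("subtype probabilities must sum to 1")
        if np.any(np.abs(self.stage_probs.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("per-subtype stage posteriors must sum to 1")
        if abs(self.stage_marginal.sum() - 1.0) > 1e-9:
            raise ValueError("marginal stage posterior must sum to 1")


def assign(Z, model: SubtypeProgressionModel) -> list[SubjectPosterior]:
    """Subtype and stage posteriors for every subject in ``Z``."""
    model._check_fitted()
    es = model._es()
    Xm = as_matrix(Z, es)
    c = len(model.sequences_)
    logm = model.log_marginals(Xm)
    lw = logm + np.log(model.fractions_)
    subtype_probs = np.exp(lw - logsumexp(lw, axis=1, keepdims=True))
    subtype_probs /= subtype_probs.sum(axis=1, keepdims=True)
    per_subtype_stage = np.stack(
        [stage_posteriors(Xm, s, model.sigma, event_set=es) for s in model.sequences_],
        axis=1,
    )  # (n, c, S+1)
    out = []
    for j in range(Xm.shape[0]):
        sp = subtype_probs[j]
        stp = per_subtype_stage[j]
        marg = sp @ stp
        marg = marg / marg.sum()
        out.append(
            SubjectPosterior(
                subtype_probs=sp,
                stage_probs=stp,
                stage_marginal=marg,
                ml_subtype=int(sp.argmax()),
                ml_stage=int(marg.argmax()),
            )
        )
    return out


def is_strong_assignment(subtype_probs, ratio: float = 1.5) -> bool:
    """Is the top subtype probability >= ``ratio`` times every other one?

    A single-subtype vector is trivially strongly assigned (logged).  Exact
    ties (e.g. the uniform vector) are not strong: 1/3 < 1.5 * 1/3.
    """
    p = np.asarray(subtype_probs, dtype=float)
    if p.ndim != 1 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("subtype_probs must be a probability vector")
    if len(p) == 1:
        logger.info("single-subtype model: strong assignment trivially true")
        return True
    top = p.argmax()
    others = np.delete(p, top)
    return bool(np.all(p[top] >= ratio * others))


def stage_distribution_by_group(
    posteriors: list[SubjectPosterior], group_labels
) -> pd.DataFrame:
    """Mean subtype-marginalized stage posterior per severity group.

    Returns a group x stage probability table; each non-empty group's row
    sums to 1.  Empty groups produce a NaN row with a warning.
    """
    labels = np.asarray(group_labels)
    if labels.shape[0] != len(posteriors):
        raise ValueError("one group label per subject is required")
    n_stages = posteriors[0].stage_marginal.shape[0]
    groups = sorted(set(labels.tolist()))
    rows = {}
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if len(idx) == 0:  # pragma: no cover - sorted(set(...)) excludes this
            warnings.warn(f"group {g!r} is empty; row set to NaN")
            rows[g] = np.full(n_stages, np.nan)
        else:
            rows[g] = np.mean([posteriors[j].stage_marginal for j in idx], axis=0)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=range(n_stages))
    df.index.name = "group"
    return df


def strong_assignment_rate_by_group(
    posteriors: list[SubjectPosterior],
    group_labels,
    ratio: float = 1.5,
) -> pd.Series:
    """Proportion of strongly assigned subjects per severity group."""
    labels = np.asarray(group_labels)
    if labels.shape[0] != len(posteriors):
        raise ValueError("one group label per subject is required")
    strong = np.array(
        [is_strong_assignment(p.subtype_probs, ratio=ratio) for p in posteriors]
    )
    out = {}
    for g in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == g)
        out[g] = float(strong[idx].mean())
    s = pd.Series(out, name="strong_assignment_rate")
    s.index.name = "group"
    return s
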