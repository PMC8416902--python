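"""Control-referenced z-scoring and biomarker selection.

Raw biomarker measurements are expressed as z-scores relative to a control
group (subjects without symptomatic or radiographic disease): z = (x - mean)
/ sd with the control-group sample mean and standard deviation.  Biomarkers
that decrease with disease progression (joint space width, cartilage
thickness) are sign-flipped so that every z-score increases with severity.

Backward deletion prunes the biomarker panel: it repeatedly removes the
biomarker whose removal most improves a cross-validated, per-biomarker
normalized held-out log likelihood, stopping when no removal improves it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.model_selection import KFold

from .events import BiomarkerDef, build_event_set

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ControlStats:
    """Per-biomarker control-group mean and standard deviation (raw scale)."""

    mean: Mapping[str, float]
    sd: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, s in self.sd.items():
            if not np.isfinite(s) or s <= 0:
                raise ValueError(f"control sd for {name!r} must be positive, got {s}")


class ZScoreScaler(BaseEstimator, TransformerMixin):
    """Transformer mapping raw measurements to direction-adjusted z-scores.

    Fit on a control-group table; transform a patient table.  The sample
    standard deviation uses the n-1 denominator.

    Parameters
    ----------
    defs : sequence of BiomarkerDef
        Biomarker definitions; defines column order and directions.

    Attributes
    ----------
    mean_, sd_ : pandas.Series
        Control-group statistics per biomarker, set by :meth:`fit`.
    """

    def __init__(self, defs: Sequence[BiomarkerDef] = ()):  # noqa: D107
        self.defs = defs

    def _columns(self) -> list[str]:
        return [d.name for d in self.defs]

    def fit(self, X: pd.DataFrame, y=None) -> "ZScoreScaler":
        cols = self._columns()
        if not cols:
            raise ValueError("defs must contain at least one biomarker definition")
        X = _check_table(X, cols, "control table")
        if len(X) < 2:
            raise ValueError("control table needs at least 2 subjects")
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        zero = [c for c in cols if sd[c] <= 0 or not np.isfinite(sd[c])]
        if zero:
            raise ValueError(
                f"control group has zero variance for biomarker(s) {zero}"
            )
        self.mean_ = mean
        self.sd_ = sd
        self.n_features_in_ = len(cols)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "mean_")
        cols = self._columns()
        X = _check_table(X, cols, "measurement table")
        direction = pd.Series({d.name: float(d.direction) for d in self.defs})
        z = direction * (X - self.mean_) / self.sd_
        return z

    def control_stats(self) -> ControlStats:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "mean_")
        return ControlStats(mean=dict(self.mean_), sd=dict(self.sd_))


def _check_table(X: pd.DataFrame, cols: Sequence[str], what: str) -> pd.DataFrame:
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float), columns=list(cols))
    missing = [c for c in cols if c not in X.columns]
    if missing:
        raise ValueError(f"{what} is missing column(s) {missing}")
    X = X.loc[:, list(cols)].astype(float)
    if X.isna().any().any():
        bad = [c for c in cols if X[c].isna().any()]
        raise ValueError(f"{what} contains missing values in column(s) {bad}")
    if not np.all(np.isfinite(X.to_numpy())):
        raise ValueError(f"{what} contains non-finite values")
    return X


def compute_control_stats(
    control_table: pd.DataFrame, defs: Sequence[BiomarkerDef] | None = None
) -> ControlStats:
    """Sample mean and sd (n-1 denominator) of each control-group column."""
    if defs is None:
        defs = [BiomarkerDef(name=c) for c in control_table.columns]
    return ZScoreScaler(defs).fit(control_table).control_stats()


def to_zscores(
    raw_table: pd.DataFrame,
    stats: ControlStats,
    defs: Sequence[BiomarkerDef],
) -> pd.DataFrame:
    """Direction-adjusted z-scores: z = direction * (x - mean) / sd."""
    scaler = ZScoreScaler(defs)
    cols = [d.name for d in defs]
    for c in cols:
        if c not in stats.mean or c not in stats.sd:
            raise ValueError(f"control stats missing biomarker {c!r}")
    scaler.mean_ = pd.Series({c: float(stats.mean[c]) for c in cols})
    scaler.sd_ = pd.Series({c: float(stats.sd[c]) for c in cols})
    scaler.n_features_in_ = len(cols)
    return scaler.transform(raw_table)


# ---------------------------------------------------------------------------
# Backward deletion


def cv_loglik_per_biomarker(
    z: pd.DataFrame,
    defs: Sequence[BiomarkerDef],
    n_folds: int = 3,
    seed: int = 0,
    min_count: int = 10,
    n_starts: int = 3,
) -> float:
    """Held-out log likelihood per biomarker of a single-sequence fit.

    Fits a one-subtype progression model on each training fold and evaluates
    the held-out fold, then divides the mean per-subject log likelihood by
    the number of biomarkers.  Total likelihoods of panels with different
    biomarker counts are not comparable; the per-biomarker normalization
    makes backward deletion well-posed.
    """
    from .inference import SubtypeProgressionModel
    from .likelihood import dataset_loglik

    cols = [d.name for d in defs]
    z = z.loc[:, cols]
    event_set = build_event_set(z, defs, min_count=min_count)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    total = 0.0
    n = 0
    for train_idx, test_idx in kf.split(z):
        model = SubtypeProgressionModel(
            event_set=event_set, n_subtypes=1, n_starts=n_starts, random_state=seed
        ).fit(z.iloc[train_idx])
        total += dataset_loglik(
            z.iloc[test_idx],
            model.sequences_,
            model.fractions_,
            model.sigma,
            event_set=event_set,
        )
        n += len(test_idx)
    return total / n / len(defs)


def backward_delete_biomarkers(
    z: pd.DataFrame,
    defs: Sequence[BiomarkerDef],
    criterion: Callable[[pd.DataFrame, Sequence[BiomarkerDef]], float] | None = None,
    min_gain: float = 1e-3,
) -> list[BiomarkerDef]:
    """Greedy backward deletion of biomarkers maximizing a fit criterion.

    Starting from the full panel, the biomarker whose removal most improves
    ``criterion`` (higher is better) is removed; the loop stops when no
    removal improves the criterion by more than ``min_gain`` or one
    biomarker remains.  The default criterion is
    :func:`cv_loglik_per_biomarker`.

    Returns the retained definitions (original order).  Removals are logged.
    """
    if len(defs) < 2:
        raise ValueError("backward deletion needs at least 2 biomarkers")
    if criterion is None:
        criterion = cv_loglik_per_biomarker
    current = list(defs)
    try:
        best = criterion(z, current)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(
            f"criterion failed on the full panel {[d.name for d in current]}"
        ) from exc
    while len(current) > 1:
        scores = []
        for i in range(len(current)):
            cand = current[:i] + current[i + 1 :]
            try:
                scores.append((criterion(z, cand), i))
            except Exception as exc:
                raise RuntimeError(
                    f"criterion failed on candidate panel {[d.name for d in cand]}"
                ) from exc
        score, idx = max(scores, key=lambda t: (t[0], -t[1]))
        if score <= best + min_gain:
            break
        logger.info(
            "backward deletion: removed %s (criterion %.4f -> %.4f)",
            current[idx].name,
            best,
            score,
        )
        best = score
        current = current[:idx] + current[idx + 1 :]
    return current
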