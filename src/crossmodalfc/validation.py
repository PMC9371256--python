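"""Cross-validation of the regional multilinear models.

Region-level validation respects spatial autocorrelation: for each region
i the N-1 off-diagonal entries of its connectivity profile are split into
train and test sets by distance to a source region s, taking the closest
75% of regions to s as train and the rest as test. Every one of the N-1
candidate source regions is used once, giving N-1 unique splits per
region (deterministic enumeration; no seed needed).

Subject-level validation is leave-one-out: the model is fitted on the
mean matrices of n-1 subjects and evaluated, region by region, on the
held-out subject (using that subject's own band profiles as predictors).

Per-split performance is the Pearson correlation between empirical and
predicted profile values, averaged over splits (or folds) per region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import BandFCSet, ConnectivityMatrix, ParcelGeometry
from .mapping import _ols

__all__ = [
    "SplitPlan",
    "CvResult",
    "distance_dependent_splits",
    "regional_cv",
    "subject_loo_cv",
]

logger = logging.getLogger(__name__)


@dataclass
class SplitPlan:
    """One distance-dependent split of region ``region``'s profile.

    ``train`` and ``test`` are positions into the off-diagonal profile
    vector (i.e. into ``np.delete(np.arange(N), region)``); ``source`` is
    the global index of the source region anchoring the split.
    """

    region: int
    source: int
    train: np.ndarray
    test: np.ndarray


@dataclass
class CvResult:
    """Per-region mean train/test correlations plus a long-format log."""

    train_map: np.ndarray
    test_map: np.ndarray
    n_splits: int
    detail: Optional[pd.DataFrame] = field(default=None, repr=False)


def distance_dependent_splits(
    geometry: ParcelGeometry, i: int, train_frac: float = 0.75
) -> list[SplitPlan]:
    """All N-1 distance-dependent splits of region ``i``'s profile.

    For each candidate source region s != i, the N-1 profile entries are
    ranked by Euclidean distance to s (s itself, at distance 0, ranks
    first) and the closest floor(train_frac * (N-1)) form the train set.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    n = geometry.n
    if not 0 <= i < n:
        raise IndexError(f"region index {i} out of range for N={n}")
    others = np.delete(np.arange(n), i)
    d = geometry.distance_matrix()[np.ix_(others, others)]
    n_obs = n - 1
    n_train = int(np.floor(train_frac * n_obs))
    plans = []
    for s_pos in range(n_obs):
        order = np.argsort(d[s_pos], kind="stable")
        plans.append(
            SplitPlan(
                region=i,
                source=int(others[s_pos]),
                train=order[:n_train],
                test=order[n_train:],
            )
        )
    return plans


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0.0:
        return np.nan
    return float(a @ b / denom)


def regional_cv(
    haemo: ConnectivityMatrix,
    bands: BandFCSet,
    geometry: ParcelGeometry,
    train_frac: float = 0.75,
    keep_detail: bool = False,
) -> CvResult:
    """Distance-dependent cross-validation of every regional model.

    Per split the model is fitted on train edges only, both train and test
    edges are predicted from the fitted coefficients, and the Pearson
    correlations between empirical and predicted values are recorded.
    Splits with a constant test target are skipped with a warning.
    """
    if not (haemo.n == bands.n == geometry.n):
        raise ValueError("haemodynamic, band, and geometry parcellations must agree")
    n = haemo.n
    train_map = np.empty(n)
    test_map = np.empty(n)
    rows = [] if keep_detail else None
    n_splits = 0
    for i in range(n):
        y = haemo.row_profile(i)
        x = bands.profiles(i)
        plans = distance_dependent_splits(geometry, i, train_frac)
        n_splits = len(plans)
        tr_vals, te_vals = [], []
        for plan in plans:
            y_tr, y_te = y[plan.train], y[plan.test]
            if np.ptp(y_te) == 0 or np.ptp(y_tr) == 0:
                logger.warning(
                    "constant target in split (region %d, source %d); skipped",
                    i,
                    plan.source,
                )
                continue
            beta, _, _ = _ols(y_tr, x[plan.train])
            pred_tr = np.column_stack([np.ones(len(plan.train)), x[plan.train]]) @ beta
            pred_te = np.column_stack([np.ones(len(plan.test)), x[plan.test]]) @ beta
            r_tr = _pearson(y_tr, pred_tr)
            r_te = _pearson(y_te, pred_te)
            tr_vals.append(r_tr)
            te_vals.append(r_te)
            if rows is not None:
                rows.append(
                    {"region": i, "source": plan.source, "train_r": r_tr, "test_r": r_te}
                )
        train_map[i] = np.mean(tr_vals)
        test_map[i] = np.mean(te_vals)
    detail = pd.DataFrame(rows) if rows is not None else None
    return CvResult(train_map=train_map, test_map=test_map, n_splits=n_splits, detail=detail)


def subject_loo_cv(
    subject_haemo: Sequence[ConnectivityMatrix],
    subject_bands: Sequence[BandFCSet],
    keep_detail: bool = False,
) -> CvResult:
    """Leave-one-subject-out cross-validation of the regional models.

    Per fold the model is fitted, region by region, on the mean matrices
    of the n-1 training subjects; train performance is the correlation of
    the fitted values with the training-mean profile, test performance the
    correlation of the held-out subject's empirical profile with the
    prediction from that subject's own band profiles.
    """
    n_subj = len(subject_haemo)
    if n_subj < 3:
        raise ValueError("need at least 3 subjects for leave-one-out validation")
    if len(subject_bands) != n_subj:
        raise ValueError("one band set per subject required")
    n = subject_haemo[0].n
    haemo_stack = np.stack([m.values for m in subject_haemo])
    band_stacks = np.stack(
        [np.stack([m.values for m in bs.matrices]) for bs in subject_bands]
    )  # (n_subj, 6, N, N)
    train_acc = np.zeros(n)
    test_acc = np.zeros(n)
    rows = [] if keep_detail else None
    for held in range(n_subj):
        mask = np.arange(n_subj) != held
        haemo_tr = haemo_stack[mask].mean(axis=0)
        bands_tr = band_stacks[mask].mean(axis=0)  # (6, N, N)
        for i in range(n):
            keep = np.arange(n) != i
            y_tr = haemo_tr[i, keep]
            x_tr = bands_tr[:, i][:, keep].T
            beta, fitted, _ = _ols(y_tr, x_tr)
            x_te = band_stacks[held, :, i][:, keep].T
            pred_te = np.column_stack([np.ones(n - 1), x_te]) @ beta
            y_te = haemo_stack[held, i, keep]
            r_tr = _pearson(y_tr, fitted)
            r_te = _pearson(y_te, pred_te)
            train_acc[i] += r_tr
            test_acc[i] += r_te
            if rows is not None:
                rows.append({"region": i, "fold": held, "train_r": r_tr, "test_r": r_te})
    detail = pd.DataFrame(rows) if rows is not None else None
    return CvResult(
        train_map=train_acc / n_subj,
        test_map=test_acc / n_subj,
        n_splits=n_subj,
        detail=detail,
    )
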