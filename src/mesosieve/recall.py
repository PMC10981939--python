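"""Reference sets and score-separation metrics (ROC/AUC, KS, ECDFs).

Builds the consensus LLPS reference (the number of curated databases listing
each protein) and quantifies how well any per-protein score separates a
reference group from the rest of the detected proteome.  Negatives are the
universe minus the positives; proteins belonging to other reference groups
are not excluded, matching how proteome-wide recall is usually plotted
(recall against fraction of the proteome accepted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .errors import InsufficientDataError, UndefinedMetricError
from .quant import ScoreVector

logger = logging.getLogger(__name__)


def merge_llps_references(membership_lists: Mapping[str, Iterable[str]]) -> pd.Series:
    """Consensus level: in how many source databases each protein appears.

    Returns an integer Series over the union of all ids.  Selecting
    ``consensus >= 4`` reproduces the conventional high-confidence LLPS
    reference rule.
    """
    if not membership_lists:
        raise UndefinedMetricError("need at least one membership list")
    counts: dict[str, int] = {}
    for _, ids in membership_lists.items():
        for pid in set(ids):
            counts[pid] = counts.get(pid, 0) + 1
    if not counts:
        logger.warning("merge_llps_references: empty union of membership lists")
        return pd.Series(dtype=int, name="llps_consensus")
    out = pd.Series(counts, name="llps_consensus").sort_index()
    return out.astype(int)


@dataclass(frozen=True)
class RocResult:
    """A ROC curve with its trapezoid AUC.

    The trapezoid AUC over the tie-grouped curve equals the Mann-Whitney
    pair statistic P(score_pos > score_neg) + 0.5 * P(equal).
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    n_positive: int
    n_negative: int


def roc_auc(
    scores: ScoreVector | pd.Series,
    positives: Iterable[str],
    universe: Iterable[str] | None = None,
) -> RocResult:
    """ROC of ``scores`` for recalling ``positives`` within ``universe``.

    Points are ranked by descending score with ties grouped.  The universe
    defaults to all scored proteins; negatives are universe minus positives.
    """
    values = scores.values if isinstance(scores, ScoreVector) else scores
    if universe is not None:
        values = values.reindex(pd.Index(sorted(set(universe))))
    values = values.dropna()
    pos = values.index.isin(set(positives))
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            f"AUC undefined: {n_pos} positives / {n_neg} negatives with finite scores"
        )
    fpr, tpr, thr = _roc_curve(pos, values.to_numpy(float), drop_intermediate=False)
    return RocResult(
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        auc=float(_trapezoid_auc(fpr, tpr)),
        n_positive=n_pos,
        n_negative=n_neg,
    )


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    Returns the maximum ECDF gap D and the two-sided p-value from the
    asymptotic Kolmogorov distribution with the standard effective-n scaling
    ``n_eff = n*m/(n+m)``.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("both samples need >= 2 finite values")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def cumulative_histogram(
    scores: ScoreVector | pd.Series,
    groups: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Per-group ECDFs of the scores on a shared grid.

    The grid is the sorted set of finite score values; each group's column is
    its empirical CDF evaluated there (nondecreasing, reaching 1).  Empty
    groups are omitted with a log message.
    """
    values = (scores.values if isinstance(scores, ScoreVector) else scores).dropna()
    grid = np.unique(values.to_numpy(float))
    out: dict[str, np.ndarray] = {}
    for name, ids in groups.items():
        member = values[values.index.isin(set(ids))].to_numpy(float)
        if member.size == 0:
            logger.info("cumulative_histogram: group %r is empty, omitted", name)
            continue
        member = np.sort(member)
        out[name] = np.searchsorted(member, grid, side="right") / member.size
    return pd.DataFrame(out, index=pd.Index(grid, name="score"))
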