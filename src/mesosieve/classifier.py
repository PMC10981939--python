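"""Bagged ensemble classifier for LLPS association.

Learns to recall known LLPS proteins (class 1, the consensus reference) from
the rest of the detected proteome (class 2) using experimental features (the
filtration and dilution fold changes) and coarsened sequence features
(disorder, nucleic-acid binding, composition).

The cross-validation scheme is partition-based rather than fold-based: many
ensembles are trained on random subsets (a large fraction of the small
class 1, a small fraction of the large class 2) and each protein's
cross-validated score is the median over the ensembles that did NOT train on
it.  This keeps every class-1 protein's score out-of-training despite the
tiny positive set.  Each ensemble bags bootstrap-resampled decision trees and
linear discriminants; trees are depth-limited (minimum leaf size, maximum
splits of three quarters the feature count) so single learners stay weak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.tree import DecisionTreeClassifier

from .errors import InvalidInputError, UndefinedMetricError
from .quant import QuantTable, ScoreVector

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------


def assemble_features(
    tables: Sequence[QuantTable],
    experimental_conditions: Sequence[str],
    seq_features: pd.DataFrame | None,
    positives: Iterable[str],
) -> tuple[pd.DataFrame, pd.Series]:
    """Build the complete feature matrix and binary labels.

    Only proteins measured in every requested experimental condition (and
    present in the sequence-feature table, if given) are kept, so the matrix
    has no missing values.  Returns ``(X, y)`` with ``y=1`` for the reference
    class.
    """
    cols: dict[str, pd.Series] = {}
    for cond in experimental_conditions:
        found = False
        for table in tables:
            if cond in table.values.columns:
                cols[cond] = table.values[cond]
                found = True
                break
        if not found:
            raise InvalidInputError(f"condition {cond!r} not found in any table")
    X = pd.DataFrame(cols)
    if seq_features is not None:
        X = X.join(seq_features, how="inner")
    X = X.dropna()
    if X.empty:
        raise InvalidInputError("no protein is complete across all feature sources")
    y = pd.Series(X.index.isin(set(positives)).astype(int), index=X.index, name="label")
    logger.info(
        "assembled %d proteins x %d features (%d in class 1)",
        X.shape[0], X.shape[1], int(y.sum()),
    )
    return X, y


# ---------------------------------------------------------------------------
# bagged ensemble
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BagParams:
    """Ensemble hyperparameters.

    ``n_learners`` bootstrap learners, alternating decision trees and linear
    discriminants (an even split by default).  Trees honour ``min_leaf``
    observations per leaf and at most ``floor(0.75 * n_features)`` splits.
    The discriminant is a two-class Gaussian discriminant with shared,
    ridge-regularized covariance.
    """

    n_learners: int = 500
    min_leaf: int = 32
    shrinkage: float = 0.05


class BaggedEnsemble:
    """Bagging of depth-limited trees and linear discriminants."""

    def __init__(self, params: BagParams | None = None, seed: int = 0) -> None:
        self.params = params or BagParams()
        self.seed = int(seed)
        self._learners: list = []
        self.max_splits_: int | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BaggedEnsemble":
        X = np.asarray(X, float)
        y = np.asarray(y, int)
        if len(np.unique(y)) < 2:
            raise InvalidInputError("training set contains a single class")
        rng = np.random.default_rng(self.seed)
        n, n_features = X.shape
        self.max_splits_ = max(1, int(np.floor(0.75 * n_features)))
        self._learners = []
        for i in range(self.params.n_learners):
            for _ in range(20):  # redraw bootstrap until both classes present
                idx = rng.integers(0, n, n)
                if len(np.unique(y[idx])) == 2:
                    break
            else:
                self._learners.append(None)  # degenerate: contributes 0.5
                continue
            if i % 2 == 0:
                learner = DecisionTreeClassifier(
                    min_samples_leaf=self.params.min_leaf,
                    max_leaf_nodes=self.max_splits_ + 1,
                    random_state=int(rng.integers(0, 2**31 - 1)),
                )
            else:
                learner = LinearDiscriminantAnalysis(
                    solver="lsqr", shrinkage=self.params.shrinkage
                )
            learner.fit(X[idx], y[idx])
            self._learners.append(learner)
        return self

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        """Mean class-1 probability over the learners, in [0, 1]."""
        if not self._learners:
            raise InvalidInputError("ensemble is not fitted")
        X = np.asarray(X, float)
        total = np.zeros(len(X))
        for learner in self._learners:
            if learner is None:
                total += 0.5
                continue
            proba = learner.predict_proba(X)
            col = list(learner.classes_).index(1)
            total += proba[:, col]
        return total / len(self._learners)


def train_bagged_ensemble(
    X: pd.DataFrame,
    y: pd.Series,
    params: BagParams | None = None,
    seed: int = 0,
) -> BaggedEnsemble:
    """Fit one bagged ensemble on the full training data."""
    model = BaggedEnsemble(params=params, seed=seed)
    model.fit(X.to_numpy(float), y.to_numpy(int))
    return model


# ---------------------------------------------------------------------------
# partition cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CrossvalResult:
    """Out-of-training ensemble scores.

    ``scores`` is the per-protein median over the ensembles that did not
    train on it; ``n_eval`` the number of such ensembles (exactly the number
    of ensembles minus the protein's training appearances); ``train_counts``
    how often each protein was used for training.  ``membership`` records
    training membership (ensembles x proteins) for leakage audits.
    """

    scores: pd.Series
    n_eval: pd.Series
    train_counts: pd.Series
    membership: np.ndarray = field(repr=False)


def crossval_scores(
    X: pd.DataFrame,
    y: pd.Series,
    n_ensembles: int = 600,
    class1_frac: float = 0.8,
    class2_frac: float = 0.1,
    params: BagParams | None = None,
    seed: int = 0,
) -> CrossvalResult:
    """Partition-based cross-validated ensemble scores.

    For each of ``n_ensembles`` random partitions, trains an ensemble on
    ``class1_frac`` of class 1 and ``class2_frac`` of class 2 (sampled
    without replacement), scores every protein, and reports each protein's
    median score over the ensembles in which it was not a training row.
    Fully reproducible from ``seed``.
    """
    if not (0 <= class1_frac <= 1 and 0 <= class2_frac <= 1):
        raise InvalidInputError("class fractions must be in [0, 1]")
    Xv = X.to_numpy(float)
    yv = y.to_numpy(int)
    idx1 = np.flatnonzero(yv == 1)
    idx2 = np.flatnonzero(yv == 0)
    if idx1.size == 0 or idx2.size == 0:
        raise InvalidInputError("both classes must be present")
    n1 = int(round(class1_frac * idx1.size))
    n2 = int(round(class2_frac * idx2.size))
    if n1 < 1 and class1_frac > 0:
        n1 = 1
    if n2 < 1 and class2_frac > 0:
        n2 = 1
    rng = np.random.default_rng(seed)

    n = len(yv)
    membership = np.zeros((n_ensembles, n), dtype=bool)
    all_scores = np.empty((n_ensembles, n), dtype=np.float32)
    for e in range(n_ensembles):
        take1 = rng.choice(idx1, size=n1, replace=False) if n1 else np.empty(0, int)
        take2 = rng.choice(idx2, size=n2, replace=False) if n2 else np.empty(0, int)
        train = np.concatenate([take1, take2]).astype(int)
        membership[e, train] = True
        learner_seed = int(rng.integers(0, 2**31 - 1))
        if len(np.unique(yv[train])) < 2:
            # a one-class partition (a class fraction of 0) cannot learn;
            # it contributes an uninformative constant score
            all_scores[e] = 0.5
            continue
        model = BaggedEnsemble(params=params, seed=learner_seed)
        model.fit(Xv[train], yv[train])
        all_scores[e] = model.predict_score(Xv)

    train_counts = membership.sum(axis=0)
    n_eval = n_ensembles - train_counts
    masked = np.ma.masked_array(all_scores, mask=membership)
    medians = np.ma.median(masked, axis=0)
    scores = np.where(n_eval > 0, np.ma.filled(medians, np.nan), np.nan)
    n_always = int((n_eval == 0).sum())
    if n_always:
        logger.warning("%d proteins were trained in every ensemble; scores missing", n_always)
    return CrossvalResult(
        scores=pd.Series(scores.astype(float), index=X.index, name="score"),
        n_eval=pd.Series(n_eval, index=X.index, name="n_eval"),
        train_counts=pd.Series(train_counts, index=X.index, name="train_count"),
        membership=membership,
    )


def combine_scores(s_exp: pd.Series, s_seq: pd.Series) -> ScoreVector:
    """Euclidean combination of experiment-only and sequence-only scores.

    Each protein's distance to the best corner,
    ``d = sqrt((max(s_exp) - s_exp)^2 + (max(s_seq) - s_seq)^2)``, is negated
    so that higher always means more LLPS-like.
    """
    aligned = pd.concat([s_exp, s_seq], axis=1, join="inner", keys=["exp", "seq"]).dropna()
    if aligned.empty:
        raise UndefinedMetricError("no protein has both component scores")
    de = aligned["exp"].max() - aligned["exp"]
    ds = aligned["seq"].max() - aligned["seq"]
    d = np.sqrt(de**2 + ds**2)
    return ScoreVector(
        values=pd.Series(-d, index=aligned.index, name="s_combined"),
        orientation="higher = more LLPS-like (negated distance to the joint best corner)",
    )
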