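"""Liquid-like behavior, the empirical replicate-noise null, and FDR classification.

The "liquid-like behavior" of a protein is its mean vertical log2 residual
from a reference line fitted through anchor proteins (canonical large
complexes and transmembrane proteins — assemblies that are retained by size
alone and do not squeeze), averaged over the selected filtration and dilution
experiments.  Positive behavior means the protein elutes more than its anchor
peers predict: the signature of deformable, dilutable assemblies.

The null model is empirical: replicate condition pairs are line-fitted in
log2 space and the pooled vertical residuals estimate the measurement-noise
distribution.  A protein is classified as condensate-organized (BMC) when its
behavior exceeds the plug-in false-discovery-rate threshold

    FDR(t) = N_total * S_null(t) / #{behavior_i >= t}  <=  fdr

where ``S_null`` is the null survival function recentred on the anchor
residuals (with a +1 tail pseudo-count), and it carries no membrane
annotation.  Proteins whose filtration fold changes stay within the
two-sided null bounds around the origin are "small" (organized below the
assayed scale).  Composition fractions over the detected proteome follow.

Vertical (not orthogonal) residuals are used throughout: the null model is
built from vertical residuals of replicate line fits, and mixing metrics
would invalidate the FDR calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    InvalidInputError,
)
from .quant import MatchedPair

logger = logging.getLogger(__name__)


@dataclass
class NoiseModel:
    """Pooled log2 residuals from replicate line fits; the empirical null."""

    residuals: np.ndarray
    n_pairs: int

    def __post_init__(self) -> None:
        self.residuals = np.sort(np.asarray(self.residuals, float))
        if not np.isfinite(self.residuals).all():
            raise InvalidInputError("null residuals must be finite")

    @property
    def median(self) -> float:
        return float(np.median(self.residuals))

    @property
    def sd(self) -> float:
        return float(np.std(self.residuals))

    def survival(self, t: np.ndarray | float, center: float = 0.0) -> np.ndarray:
        """P(null > t) with the null median aligned to ``center``.

        Uses a +1 pseudo-count in the tail so the extreme tail never
        estimates exactly zero.
        """
        shifted = self.residuals - self.median + center
        t = np.asarray(t, float)
        n_above = len(shifted) - np.searchsorted(shifted, t, side="right")
        return (n_above + 1) / (len(shifted) + 1)

    def two_sided_bound(self, level: float) -> float:
        """Half-width of the central ``1 - level`` interval of |null - median|."""
        return float(np.quantile(np.abs(self.residuals - self.median), 1.0 - level))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n values from the (median-centred) empirical null."""
        return rng.choice(self.residuals - self.median, size=n, replace=True)


def build_noise_model(pairs: Sequence[MatchedPair]) -> NoiseModel:
    """Fit a log2 line through each replicate pair and pool the residuals.

    Each matched pair contributes the vertical residuals of an OLS fit of
    log2(y) on log2(x) over its shared finite measurements.
    """
    if not pairs:
        raise InsufficientDataError("cannot build a noise model from zero pairs")
    residuals: list[np.ndarray] = []
    for pair in pairs:
        with np.errstate(divide="ignore", invalid="ignore"):
            lx = np.log2(pair.x.to_numpy(float))
            ly = np.log2(pair.y.to_numpy(float))
        ok = np.isfinite(lx) & np.isfinite(ly)
        lx, ly = lx[ok], ly[ok]
        if len(lx) < 3:
            continue
        if np.ptp(lx) == 0:
            residuals.append(ly - np.mean(ly))
            continue
        slope, icept = np.polyfit(lx, ly, 1)
        residuals.append(ly - (slope * lx + icept))
    if not residuals:
        raise InsufficientDataError("no pair had enough finite measurements")
    pooled = np.concatenate(residuals)
    logger.info("noise model: %d pairs, %d residuals, sd=%.4f", len(pairs), len(pooled), pooled.std())
    return NoiseModel(residuals=pooled, n_pairs=len(pairs))


@dataclass
class LiquidBehavior:
    """Per-protein liquid-like behavior with classification flags.

    ``table`` has columns ``behavior`` (mean log2 shift), ``n_used``
    (experiments contributing) and, after :func:`fdr_classify`, the boolean
    flags ``bmc_positive``, ``small`` and ``membrane_excluded``.
    """

    table: pd.DataFrame
    anchor_ids: frozenset
    per_experiment: pd.DataFrame = field(repr=False)
    threshold: float | None = None
    small_bound: float | None = None
    fdr: float | None = None


def liquid_behavior(
    scatters: Mapping[str, tuple[pd.Series, pd.Series]],
    anchor_ids: Iterable[str],
) -> LiquidBehavior:
    """Mean anchor-line residual per protein across experiments.

    ``scatters`` maps an experiment name to an ``(x, y)`` pair of fold-change
    Series (reference condition, responsive condition): early vs late window
    for filtration chromatography, undiluted vs diluted for dilution
    experiments.  Per experiment, an OLS line in log2 space is fitted through
    the anchor proteins only and every protein's signed vertical residual
    from it is recorded (positive = elutes more than the anchors predict);
    ``behavior`` is the mean residual over the experiments in which the
    protein is measured.
    """
    anchors = frozenset(anchor_ids)
    if not anchors:
        raise InvalidInputError("anchor set is empty")
    residual_cols: dict[str, pd.Series] = {}
    for name, (x, y) in scatters.items():
        aligned = pd.concat([x, y], axis=1, join="inner", keys=["x", "y"])
        with np.errstate(divide="ignore", invalid="ignore"):
            lx = np.log2(aligned["x"].to_numpy(float))
            ly = np.log2(aligned["y"].to_numpy(float))
        ok = np.isfinite(lx) & np.isfinite(ly)
        idx = aligned.index[ok]
        lx, ly = lx[ok], ly[ok]
        is_anchor = idx.isin(anchors)
        if is_anchor.sum() < 2:
            raise InsufficientDataError(
                f"experiment {name!r}: fewer than 2 anchor proteins measured"
            )
        ax, ay = lx[is_anchor], ly[is_anchor]
        if np.ptp(ax) == 0:
            raise DegenerateDataError(f"experiment {name!r}: anchor x-values are constant")
        slope, icept = np.polyfit(ax, ay, 1)
        residual_cols[name] = pd.Series(ly - (slope * lx + icept), index=idx)
        logger.info(
            "experiment %s: anchor line slope=%.3f intercept=%.3f (%d anchors, %d proteins)",
            name, slope, icept, int(is_anchor.sum()), len(idx),
        )
    per_experiment = pd.DataFrame(residual_cols)
    table = pd.DataFrame(
        {
            "behavior": per_experiment.mean(axis=1),
            "n_used": per_experiment.notna().sum(axis=1).astype(int),
        }
    )
    table.index.name = "protein_id"
    return LiquidBehavior(table=table, anchor_ids=anchors, per_experiment=per_experiment)


def fdr_classify(
    behavior: LiquidBehavior,
    noise: NoiseModel,
    fdr: float = 0.02,
    membrane_ids: Iterable[str] = (),
    filtration_log2: pd.DataFrame | None = None,
    method: str = "plugin",
) -> LiquidBehavior:
    """Flag BMC-positive and small proteins at the given FDR level.

    With ``method="plugin"`` (default) the threshold is the smallest observed
    behavior value ``t`` with estimated ``FDR(t) = N_total * S_null(t) /
    #{behavior >= t} <= fdr`` (the qualifying set grows with ``fdr``, so
    positive sets nest).  ``method="tail"`` instead thresholds at the null's
    upper ``fdr`` tail quantile — a per-comparison rate, not a discovery-set
    rate; both readings of a "2% false discovery rate of the null model" are
    exposed because sources differ on which is meant.  The null survival
    function is median-aligned to the anchor residual distribution before
    tail comparison.  ``bmc_positive`` requires no membrane annotation.
    ``small`` holds when the protein's mean log2 filtration fold change
    (columns of ``filtration_log2``) lies within the two-sided null bound at
    the same level.
    """
    if not (0 < fdr <= 1):
        raise InvalidInputError(f"fdr must be in (0, 1], got {fdr}")
    if method not in ("plugin", "tail"):
        raise InvalidInputError(f"method must be 'plugin' or 'tail', got {method!r}")
    table = behavior.table.copy()
    b = table["behavior"].to_numpy(float)
    measured = np.isfinite(b)
    n_total = int(measured.sum())
    if n_total == 0:
        raise InsufficientDataError("no protein has a finite behavior value")

    anchor_behaviors = table.loc[table.index.isin(behavior.anchor_ids), "behavior"].dropna()
    center = float(np.median(anchor_behaviors)) if len(anchor_behaviors) else 0.0

    if method == "plugin":
        observed = np.sort(b[measured])
        n_at_least = n_total - np.arange(n_total)  # #{behavior >= observed[k]}
        est_fdr = np.minimum(
            1.0, n_total * noise.survival(observed, center=center) / n_at_least
        )
        qualifying = observed[est_fdr <= fdr]
        threshold = float(qualifying.min()) if qualifying.size else np.inf
        if not np.isfinite(threshold):
            logger.info("no threshold achieves FDR <= %g; zero positives", fdr)
    else:
        threshold = float(
            np.quantile(noise.residuals - noise.median + center, 1.0 - fdr)
        )

    membranes = set(membrane_ids)
    is_membrane = table.index.isin(membranes)
    table["membrane_excluded"] = is_membrane
    table["bmc_positive"] = measured & (b >= threshold) & ~is_membrane

    small_bound = noise.two_sided_bound(fdr)
    if filtration_log2 is not None:
        mean_fc = filtration_log2.mean(axis=1).reindex(table.index)
        table["small"] = mean_fc.abs().le(small_bound) & mean_fc.notna()
    else:
        table["small"] = False
    logger.info(
        "fdr_classify: threshold=%.4f, %d BMC-positive, %d small (bound %.4f) of %d",
        threshold, int(table["bmc_positive"].sum()), int(table["small"].sum()),
        small_bound, len(table),
    )
    return LiquidBehavior(
        table=table,
        anchor_ids=behavior.anchor_ids,
        per_experiment=behavior.per_experiment,
        threshold=threshold,
        small_bound=small_bound,
        fdr=fdr,
    )


@dataclass(frozen=True)
class CompositionReport:
    """Proteome composition over detected proteins; fractions sum to 1."""

    fractions: dict
    members: dict
    n_detected: int


def proteome_fractions(
    behavior: LiquidBehavior,
    annotations: pd.DataFrame,
) -> CompositionReport:
    """Partition the detected proteome into MBO / BMC / small / unassigned.

    Membrane-bound-organelle membership comes from annotation; BMC from the
    ``bmc_positive`` flag; small from the ``small`` flag; the remainder is
    unassigned.  Categories are disjoint in that priority order and the four
    fractions sum to exactly 1 over the detected proteins.
    """
    table = behavior.table
    if "bmc_positive" not in table.columns:
        raise InvalidInputError("behavior has no flags; run fdr_classify first")
    idx = table.index
    mbo = annotations["membrane_bound_organelle"].reindex(idx).fillna(False).astype(bool)
    bmc = table["bmc_positive"].astype(bool) & ~mbo
    small = table["small"].astype(bool) & ~mbo & ~bmc
    unassigned = ~(mbo | bmc | small)
    n = len(idx)
    members = {
        "membrane_bound_organelle": list(idx[mbo]),
        "bmc": list(idx[bmc]),
        "small": list(idx[small]),
        "unassigned": list(idx[unassigned]),
    }
    fractions = {k: len(v) / n if n else 0.0 for k, v in members.items()}
    return CompositionReport(fractions=fractions, members=members, n_detected=n)
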