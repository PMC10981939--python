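"""Fold-change tables: the pipeline's central container and its basic algebra.

A :class:`QuantTable` holds a protein x condition matrix of fold changes
FC = c/c0 (filtrate concentration relative to input; 1 means free passage)
together with per-condition metadata (experiment name, pore size, dilution,
sampling window, replicate).  Condition columns are named
``<experiment>|<condition>``, e.g. ``filt30_r1|T1``.

Operations follow the measurement conventions of multiplexed (TMT) filtration
proteomics: per-experiment normalization to the 0.95 quantile (the freely
passing proteins define unit fold change, absorbing channel-loading
imbalance), log2 condition ratios, and replicate matching by Pearson
correlation in log2 space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateDataError,
    FormatError,
    InvalidInputError,
)

logger = logging.getLogger(__name__)

_METADATA_COLUMNS = ["experiment", "pore_nm", "dilution", "window_start", "window_end", "replicate"]


@dataclass
class QuantTable:
    """Protein x condition fold-change matrix with condition metadata.

    ``values`` is indexed by ``protein_id`` (unique) with one column per
    condition; every column must have a metadata row in ``conditions``
    (indexed by condition name).  Values are nonnegative; missing measurements
    are NaN and are propagated, never imputed.
    """

    values: pd.DataFrame
    conditions: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(f"duplicate protein ids: {list(dupes[:5])}")
        missing_meta = [c for c in self.values.columns if c not in self.conditions.index]
        if missing_meta:
            raise FormatError(
                f"conditions missing from metadata: {missing_meta}"
            )
        finite = self.values.to_numpy(float)
        if np.nanmin(finite, initial=0.0) < 0:
            raise InvalidInputError("fold changes must be >= 0")

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    def experiments(self) -> list[str]:
        """Distinct experiment names, in metadata order."""
        seen: dict[str, None] = {}
        for cond in self.values.columns:
            seen.setdefault(str(self.conditions.loc[cond, "experiment"]), None)
        return list(seen)

    def columns_for_experiment(self, experiment: str) -> list[str]:
        return [
            c
            for c in self.values.columns
            if str(self.conditions.loc[c, "experiment"]) == experiment
        ]

    def copy(self) -> "QuantTable":
        return QuantTable(self.values.copy(), self.conditions.copy(), self.normalized)


def merge_quant_tables(tables: Sequence[QuantTable]) -> QuantTable:
    """Column-concatenate tables sharing one protein index."""
    if not tables:
        raise InvalidInputError("no tables to merge")
    base = tables[0].values.index
    for t in tables[1:]:
        if not base.equals(t.values.index):
            raise InvalidInputError("tables must share an identical protein index")
    values = pd.concat([t.values for t in tables], axis=1)
    conditions = pd.concat([t.conditions for t in tables], axis=0)
    if values.columns.duplicated().any():
        raise InvalidInputError("duplicate condition names across tables")
    normalized = all(t.normalized for t in tables)
    return QuantTable(values=values, conditions=conditions, normalized=normalized)


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------


def write_quant_table(table: QuantTable, path: str | Path, conditions_path: str | Path) -> None:
    """Write the matrix and its condition metadata as UTF-8 TSV files.

    Finite values round-trip bit-exactly through :func:`read_quant_table`
    (floats are written with full repr precision); missing cells are empty
    fields.
    """
    values = table.values.copy()
    values.index.name = "protein_id"
    values.to_csv(path, sep="\t", encoding="utf-8", na_rep="")
    conditions = table.conditions.copy()
    conditions.index.name = "condition"
    conditions.to_csv(conditions_path, sep="\t", encoding="utf-8", na_rep="")


def read_quant_table(path: str | Path, conditions_path: str | Path) -> QuantTable:
    """Read a matrix TSV plus conditions TSV written by this package.

    Unknown metadata columns are preserved.  Duplicate protein ids or a
    matrix condition absent from the metadata raise :class:`FormatError`
    naming the offender.
    """
    values = pd.read_csv(
        path, sep="\t", index_col="protein_id", encoding="utf-8",
        float_precision="round_trip",
    )
    conditions = pd.read_csv(
        conditions_path, sep="\t", index_col="condition", encoding="utf-8",
        float_precision="round_trip",
    )
    return QuantTable(values=values, conditions=conditions)


# ---------------------------------------------------------------------------
# normalization and ratios
# ---------------------------------------------------------------------------


def normalize_q95(table: QuantTable, quantile: float = 0.95) -> QuantTable:
    """Normalize each experiment to its pooled 0.95 quantile.

    All values of the condition columns belonging to one experiment are
    pooled; every value is divided by the pooled ``quantile`` (linear
    interpolation between order statistics).  Afterwards that pooled quantile
    equals 1 — the freely passing proteins, which populate the top of each
    experiment's fold-change distribution, define unit fold change.  This
    cancels any per-experiment scale factor exactly (scale equivariance) and
    thereby the loading imbalance shared within an experiment.
    """
    if table.normalized:
        raise InvalidInputError("table is already normalized")
    values = table.values.copy()
    for experiment in table.experiments():
        cols = table.columns_for_experiment(experiment)
        pooled = values[cols].to_numpy(float).ravel()
        pooled = pooled[np.isfinite(pooled)]
        if pooled.size == 0:
            raise DegenerateDataError(f"experiment {experiment!r} has no finite values")
        q = float(np.quantile(pooled, quantile))
        if q == 0:
            raise DegenerateDataError(
                f"experiment {experiment!r} has zero {quantile} quantile"
            )
        values[cols] = values[cols] / q
        logger.debug("normalized experiment %s by q%g=%g", experiment, quantile, q)
    return QuantTable(values=values, conditions=table.conditions.copy(), normalized=True)


@dataclass
class ScoreVector:
    """A per-protein scalar score with an explicit orientation convention."""

    values: pd.Series
    orientation: str

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise InvalidInputError("duplicate protein ids in score vector")
        if not self.orientation:
            raise InvalidInputError("orientation must be stated")


def condition_ratio(table: QuantTable, cond_a: str, cond_b: str) -> ScoreVector:
    """Per-protein log2 ratio of two conditions (``a`` over ``b``).

    Missing if either measurement is missing; zero denominators yield missing
    values and are counted in a warning.  Orientation: higher means more
    signal in ``cond_a``.
    """
    for cond in (cond_a, cond_b):
        if cond not in table.values.columns:
            raise InvalidInputError(f"condition {cond!r} not in table")
    a = table.values[cond_a].to_numpy(float)
    b = table.values[cond_b].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(a / b)
    zero_den = np.isfinite(a) & (b == 0)
    if zero_den.any():
        logger.warning(
            "condition_ratio(%s, %s): %d zero denominators set to missing",
            cond_a,
            cond_b,
            int(zero_den.sum()),
        )
    ratio[~np.isfinite(ratio)] = np.nan
    return ScoreVector(
        values=pd.Series(ratio, index=table.values.index, name=f"log2({cond_a}/{cond_b})"),
        orientation=f"higher = more in {cond_a}",
    )


# ---------------------------------------------------------------------------
# replicate matching
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MatchedPair:
    """Two replicate condition columns with their aligned measurements."""

    table_a: int
    condition_a: str
    table_b: int
    condition_b: str
    r: float
    n_shared: int
    x: pd.Series = field(compare=False, repr=False)
    y: pd.Series = field(compare=False, repr=False)


def _comparability_key(meta: pd.Series) -> tuple:
    # conditions are comparable when pore, dilution and window agree; the
    # replicate id and experiment name may differ
    def _norm(v):
        try:
            f = float(v)
        except (TypeError, ValueError):
            return str(v)
        return "nan" if np.isnan(f) else round(f, 9)

    return tuple(_norm(meta.get(k)) for k in ("pore_nm", "dilution", "window_start", "window_end"))


def match_replicates(
    tables: Sequence[QuantTable],
    r_min: float = 0.8,
    min_shared: int = 3,
) -> list[MatchedPair]:
    """All cross-pairs of comparable conditions correlating above ``r_min``.

    Conditions are comparable when they measure the same physical condition
    (same pore size, dilution and sampling window); a column is never paired
    with itself and each unordered pair is listed once.  Correlation is
    pairwise-complete Pearson of log2 values; pairs sharing fewer than
    ``min_shared`` finite proteins are skipped with a log message.
    """
    if not (0 < r_min < 1):
        raise InvalidInputError(f"r_min must be in (0, 1), got {r_min}")
    columns: list[tuple[int, str, tuple, pd.Series]] = []
    for ti, table in enumerate(tables):
        for cond in table.values.columns:
            key = _comparability_key(table.conditions.loc[cond])
            columns.append((ti, cond, key, table.values[cond]))

    pairs: list[MatchedPair] = []
    for i in range(len(columns)):
        ti, ci, ki, xi = columns[i]
        for j in range(i + 1, len(columns)):
            tj, cj, kj, xj = columns[j]
            if ki != kj:
                continue
            aligned = pd.concat([xi, xj], axis=1, join="inner", keys=["x", "y"])
            with np.errstate(divide="ignore", invalid="ignore"):
                lx = np.log2(aligned["x"].to_numpy(float))
                ly = np.log2(aligned["y"].to_numpy(float))
            ok = np.isfinite(lx) & np.isfinite(ly)
            if ok.sum() < min_shared:
                logger.info(
                    "skipping pair (%s, %s): only %d shared proteins", ci, cj, int(ok.sum())
                )
                continue
            r = float(np.corrcoef(lx[ok], ly[ok])[0, 1])
            if r > r_min:
                pairs.append(
                    MatchedPair(
                        table_a=ti,
                        condition_a=ci,
                        table_b=tj,
                        condition_b=cj,
                        r=r,
                        n_shared=int(ok.sum()),
                        x=aligned["x"][ok],
                        y=aligned["y"][ok],
                    )
                )
    logger.info("matched %d replicate pairs at r > %g", len(pairs), r_min)
    return pairs
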