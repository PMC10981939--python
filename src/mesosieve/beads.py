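"""Size-exclusion bead analysis: fill fractions, step CV, Stokes-Einstein sizes.

Porous chromatography beads of defined cutoff sizes exclude assemblies larger
than their pores.  The background-corrected fluorescence intensity of a
labelled protein inside a bead, relative to the outside solution and
corrected for the bead's accessible volume (measured with a small dextran
tracer), is its *fill fraction* — a proxy for the mass fraction of its
assemblies smaller than the cutoff.  Profiling fill fractions across an
ascending series of cutoffs yields a coarse cumulative assembly-size
distribution; the coefficient of variation of its successive steps
distinguishes organization concentrated at one scale (one dominant step, high
CV) from organization spread across the mesoscale (even steps, low CV).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.constants import Boltzmann

from .errors import InvalidInputError, UndefinedMetricError

logger = logging.getLogger(__name__)


def accessible_volume(dextran_in: float, dextran_out: float) -> float:
    """Accessible-volume fraction rho0 from the dextran intensity ratio."""
    if dextran_out <= 0:
        raise InvalidInputError("outside dextran intensity must be > 0")
    if dextran_in < 0:
        raise InvalidInputError("inside dextran intensity must be >= 0")
    rho0 = dextran_in / dextran_out
    if rho0 > 1:
        logger.warning("accessible volume %.3f > 1; check background correction", rho0)
    return rho0


def fill_fraction(i_in: float | np.ndarray, i_out: float | np.ndarray, rho0: float) -> np.ndarray:
    """Fill fraction f = I_in / (I_out * rho0).

    Not clamped: values slightly above 1 are legitimate measurement noise and
    must survive for the step-CV metric.
    """
    i_out = np.asarray(i_out, float)
    if np.any(i_out <= 0) or rho0 <= 0:
        raise InvalidInputError("I_out and rho0 must be > 0")
    return np.asarray(i_in, float) / (i_out * rho0)


def step_cv(
    cutoffs: Sequence[float],
    fills: Sequence[float],
    extrapolate_to: float | None = 1000.0,
) -> float:
    """Coefficient of variation of the successive fill-fraction steps.

    The step set is the increments of the cumulative profile from 0, through
    the fill values at the sorted cutoffs, to 1 at ``extrapolate_to`` (the
    scale where microscopy shows no residual organization; pass ``None`` to
    drop the extrapolation anchor).  CV = population SD / mean of the steps.
    A single dominant step (organization at one scale) gives a high CV; an
    assembly-size distribution spanning the sampled scales gives a low CV.
    """
    cutoffs = np.asarray(cutoffs, float)
    fills = np.asarray(fills, float)
    if cutoffs.shape != fills.shape or len(cutoffs) < 2:
        raise InvalidInputError("need matching cutoffs and fills with >= 2 entries")
    order = np.argsort(cutoffs)
    profile = fills[order]
    levels = np.concatenate([[0.0], profile, [1.0]]) if extrapolate_to is not None else np.concatenate([[0.0], profile])
    steps = np.diff(levels)
    mean = steps.mean()
    if mean <= 0:
        raise UndefinedMetricError("mean step is not positive; CV undefined")
    return float(steps.std() / mean)


def bead_report(
    profiles: pd.DataFrame,
    extrapolate_to: float | None = 1000.0,
) -> pd.DataFrame:
    """Fill fractions and step CV per species from a bead intensity table.

    ``profiles`` needs columns ``species_id, cutoff_nm, I_in, I_out`` and
    ``is_calibration`` marking the dextran rows used to determine the
    accessible volume per cutoff.  Returns a tidy table of fill fractions
    with a per-species ``step_cv`` column attached.
    """
    required = {"species_id", "cutoff_nm", "I_in", "I_out", "is_calibration"}
    missing = required - set(profiles.columns)
    if missing:
        raise InvalidInputError(f"profiles table missing columns: {sorted(missing)}")
    cal = profiles[profiles["is_calibration"]]
    if cal.empty:
        raise InvalidInputError("no calibration (dextran) rows in profiles table")
    rho0_per_cutoff = {
        float(s): accessible_volume(g["I_in"].mean(), g["I_out"].mean())
        for s, g in cal.groupby("cutoff_nm")
    }
    rows = []
    data = profiles[~profiles["is_calibration"]]
    for sid, g in data.groupby("species_id", sort=True):
        g = g.sort_values("cutoff_nm")
        fills = [
            float(fill_fraction(r["I_in"], r["I_out"], rho0_per_cutoff[float(r["cutoff_nm"])]))
            for _, r in g.iterrows()
        ]
        cv = step_cv(g["cutoff_nm"].to_list(), fills, extrapolate_to=extrapolate_to)
        for (_, r), f in zip(g.iterrows(), fills):
            rows.append(
                {
                    "species_id": sid,
                    "cutoff_nm": float(r["cutoff_nm"]),
                    "fill": f,
                    "rho0": rho0_per_cutoff[float(r["cutoff_nm"])],
                    "step_cv": cv,
                }
            )
    return pd.DataFrame(rows)


def stokes_einstein_radius(
    diffusion_um2_s: float,
    temperature_k: float = 298.0,
    viscosity_pa_s: float = 8.9e-4,
) -> float:
    """Hydrodynamic radius (nm) from a diffusion constant via Stokes-Einstein.

    ``r = k_B * T / (6 pi eta D)`` with D given in um^2/s.
    """
    if diffusion_um2_s <= 0 or temperature_k <= 0 or viscosity_pa_s <= 0:
        raise InvalidInputError("all inputs must be > 0")
    d_m2_s = diffusion_um2_s * 1e-12
    r_m = Boltzmann * temperature_k / (6.0 * np.pi * viscosity_pa_s * d_m2_s)
    return float(r_m * 1e9)


def calibrated_radius(r_ref_nm: float, d_ref: float, d: float) -> float:
    """Radius from a reference species of known size: r = r_ref * D_ref / D."""
    if r_ref_nm <= 0 or d_ref <= 0 or d <= 0:
        raise InvalidInputError("all inputs must be > 0")
    return r_ref_nm * d_ref / d
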