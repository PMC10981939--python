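"""Synthetic cytoplasm: forward simulation of filtration proteomics with ground truth.

This module generates a proteome of four species classes — freely diffusing
proteins, rigid macromolecular complexes, deformable biomolecular condensates
(with a saturation concentration and a non-dissolving solid core), and
membrane-bound organelles — and simulates the assays the analysis modules
consume:

* filtration chromatography (pore-size- and time-dependent elution),
* dilution filtration (condensates shrink as c0/f approaches c_sat),
* hard-spin sedimentation (large assemblies deplete from the top),
* size-exclusion bead partitioning (fill fractions from an assembly-size
  distribution),
* class-correlated sequence features (disorder, nucleic-acid binding,
  composition) and reference annotations with an LLPS consensus level.

Every operation draws from an independent random stream derived from its seed,
so adding one simulation to a script does not perturb the others.

Elution model
-------------
A species with effective assembly diameter ``d_eff`` at pore cutoff ``d_pore``
elutes with instantaneous filtrate concentration (relative to input, so 1 means
free passage)::

    d_eff <= d_pore          FC(t) = 1
    rigid,      d_eff > d_pore   FC(t) = leak
    deformable, d_eff > d_pore   FC(t) = 0 for t < t_on, else 1 - exp(-(t - t_on)/tau)

with onset ``t_on = min(1, beta * (d_eff/d_pore - 1) / lam)`` and squeezing time
``tau = tau0 * (d_eff/d_pore) / lam``, where ``lam`` in (0, 1] is the species'
deformability.  Time is measured as a fraction of the total spin.  A sampled
window's value is the mean of FC(t) over the window; retained species are
floored at ``leak`` (a detection/leakage floor — measured fold changes of
heavily retained proteins are small but finite, never exactly zero).

Dilution acts through the condensed fraction ``phi(f) = max(phi_core,
1 - f/c_ratio)`` (``c_ratio = c0/c_sat``): assemblies shrink with cube-root
mass scaling ``d_eff = max(d_mono, d0 * (phi(f)/phi(1))**(1/3))`` and species
with ``phi_core = 1`` are dilution-invariant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import InvalidConfigError, InvalidInputError, InvalidTruthError
from .quant import QuantTable

logger = logging.getLogger(__name__)

CLASSES = ("free", "complex", "condensate", "membrane_organelle")

#: Default class composition of the simulated proteome.  Mirrors the measured
#: cytoplasmic partition: ~40% membrane-bound organelle proteins, ~25% in
#: condensates, ~12% small/free, remainder in large complexes.
DEFAULT_CLASS_FRACTIONS: Mapping[str, float] = {
    "free": 0.12,
    "condensate": 0.25,
    "membrane_organelle": 0.40,
    "complex": 0.23,
}

#: Per-class parameter ranges (diameters in nm).  ``d0`` is sampled
#: log-uniformly, everything else uniformly.  Condensates assemble on the
#: ~100 nm mesoscale; complexes span the ribosome-to-vault scale; organelles
#: are well above every pore cutoff.
DEFAULT_PARAM_RANGES: Mapping[str, Mapping[str, tuple[float, float]]] = {
    "free": {"d0": (2.0, 8.0)},
    "complex": {"d_mono": (3.0, 6.0), "d0": (32.0, 90.0)},
    "condensate": {
        "d_mono": (3.0, 8.0),
        "d0": (60.0, 120.0),
        "c_ratio": (1.5, 4.0),
        "phi_core": (0.1, 0.5),
        "lam": (0.6, 1.0),
    },
    "membrane_organelle": {"d_mono": (4.0, 10.0), "d0": (200.0, 1000.0)},
}

# Per-operation salts for seed splitting (arbitrary, fixed).
_SALT_PROTEOME = 101
_SALT_NOISE = 211
_SALT_FEATURES = 307
_SALT_ANNOTATIONS = 401
_SALT_BEADS = 503
_SALT_SEDIMENT = 601


def _rng(seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), salt)))


# ---------------------------------------------------------------------------
# configuration objects
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ElutionConfig:
    """One filtration experiment: a pore size, a dilution, sampling windows.

    ``windows`` are ``(t_start, t_end)`` fractions of the total spin time in
    [0, 1]; ``labels`` names the matching condition columns (default T1..Tk).
    """

    name: str
    d_pore: float
    windows: Sequence[tuple[float, float]]
    dilution: float = 1.0
    labels: Sequence[str] | None = None
    beta: float = 0.2
    tau0: float = 0.15
    leak: float = 0.02
    pore_width: float = 0.2
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.d_pore <= 0:
            raise InvalidConfigError(f"d_pore must be > 0, got {self.d_pore}")
        if self.dilution < 1:
            raise InvalidConfigError(f"dilution must be >= 1, got {self.dilution}")
        if not (0 <= self.leak < 1):
            raise InvalidConfigError(f"leak must be in [0, 1), got {self.leak}")
        if self.pore_width <= 0:
            raise InvalidConfigError(f"pore_width must be > 0, got {self.pore_width}")
        prev_end = -np.inf
        for start, end in self.windows:
            if not (0 <= start < end <= 1):
                raise InvalidConfigError(f"window [{start}, {end}] not within [0, 1]")
            if start < prev_end:
                raise InvalidConfigError("windows must be ordered and non-overlapping")
            prev_end = end
        if self.labels is not None and len(self.labels) != len(self.windows):
            raise InvalidConfigError("labels must match windows")

    @property
    def window_labels(self) -> list[str]:
        if self.labels is not None:
            return list(self.labels)
        return [f"T{i + 1}" for i in range(len(self.windows))]


@dataclass(frozen=True)
class NoiseConfig:
    """Log2-multiplicative measurement noise.

    ``sigma_channel`` is the SD of independent per-measurement noise;
    ``sigma_loading`` the SD of a per-condition (TMT-channel-like) loading
    factor shared by a whole column.  Both in log2 units.
    """

    sigma_channel: float = 0.1
    sigma_loading: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_channel < 0 or self.sigma_loading < 0:
            raise InvalidConfigError("noise sigmas must be >= 0")


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


def generate_proteome(
    n_species: int,
    class_fractions: Mapping[str, float] | None = None,
    param_ranges: Mapping[str, Mapping[str, tuple[float, float]]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a ground-truth proteome of ``n_species`` species.

    Class counts are multinomial in ``class_fractions``; per-class physical
    parameters are drawn from ``param_ranges`` (log-uniform for ``d0``,
    uniform otherwise).  Returns a DataFrame indexed by ``species_id`` with
    columns ``class, d0, d_mono, c_ratio, phi_core, lam, abundance``.
    Identical seeds reproduce the table exactly.
    """
    if n_species < 0:
        raise InvalidInputError(f"n_species must be >= 0, got {n_species}")
    fractions = dict(class_fractions or DEFAULT_CLASS_FRACTIONS)
    unknown = set(fractions) - set(CLASSES)
    if unknown:
        raise InvalidConfigError(f"unknown species classes: {sorted(unknown)}")
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise InvalidConfigError(f"class fractions must sum to 1, got {total!r}")
    ranges = {**{k: dict(v) for k, v in DEFAULT_PARAM_RANGES.items()}}
    for cls, rng_map in (param_ranges or {}).items():
        ranges.setdefault(cls, {}).update(rng_map)

    rng = _rng(seed, _SALT_PROTEOME)
    probs = [fractions.get(cls, 0.0) for cls in CLASSES]
    counts = rng.multinomial(n_species, probs)
    classes = np.repeat(CLASSES, counts)

    def _uniform(cls: str, key: str, size: int, log: bool = False) -> np.ndarray:
        lo, hi = ranges[cls][key]
        if log:
            return np.exp(rng.uniform(np.log(lo), np.log(hi), size))
        return rng.uniform(lo, hi, size)

    rows: list[pd.DataFrame] = []
    offset = 0
    for cls, count in zip(CLASSES, counts):
        if count == 0:
            continue
        d0 = _uniform(cls, "d0", count, log=True)
        if cls == "free":
            d_mono = d0.copy()  # a free species is its own monomer
        else:
            d_mono = np.minimum(_uniform(cls, "d_mono", count), d0)
        if cls == "condensate":
            c_ratio = _uniform(cls, "c_ratio", count)
            phi_core = _uniform(cls, "phi_core", count)
            lam = _uniform(cls, "lam", count)
        else:
            c_ratio = np.full(count, np.nan)
            phi_core = np.full(count, np.nan)
            lam = np.zeros(count)
        abundance = np.exp(rng.normal(0.0, 1.0, count))
        ids = [f"P{offset + i:05d}" for i in range(count)]
        offset += count
        rows.append(
            pd.DataFrame(
                {
                    "class": cls,
                    "d0": d0,
                    "d_mono": d_mono,
                    "c_ratio": c_ratio,
                    "phi_core": phi_core,
                    "lam": lam,
                    "abundance": abundance,
                },
                index=pd.Index(ids, name="species_id"),
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["class", "d0", "d_mono", "c_ratio", "phi_core", "lam", "abundance"],
            index=pd.Index([], name="species_id"),
        )
    return pd.concat(rows)


def effective_diameter(truth: pd.DataFrame, dilution: float) -> pd.Series:
    """Assembly diameter of every species at the given dilution factor.

    Condensates partially dissolve: the condensed fraction is
    ``phi(f) = max(phi_core, 1 - f/c_ratio)`` and the representative assembly
    shrinks with cube-root mass scaling, never below the monomer diameter.
    Rigid classes and free species are dilution-invariant.
    """
    if dilution < 1:
        raise InvalidInputError(f"dilution must be >= 1, got {dilution}")
    d_eff = truth["d0"].astype(float).copy()
    cond = truth["class"] == "condensate"
    if cond.any():
        c_ratio = truth.loc[cond, "c_ratio"].to_numpy(float)
        phi_core = truth.loc[cond, "phi_core"].to_numpy(float)
        phi1 = np.maximum(phi_core, 1.0 - 1.0 / c_ratio)
        phif = np.maximum(phi_core, 1.0 - dilution / c_ratio)
        d0 = truth.loc[cond, "d0"].to_numpy(float)
        d_mono = truth.loc[cond, "d_mono"].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(phi1 > 0, (phif / phi1) ** (1.0 / 3.0), 0.0)
        d_eff.loc[cond] = np.maximum(d_mono, d0 * scale)
    return d_eff


# ---------------------------------------------------------------------------
# elution
# ---------------------------------------------------------------------------


def _window_mean_after_onset(t_on: np.ndarray, tau: np.ndarray, a: float, b: float) -> np.ndarray:
    """Mean of ``1 - exp(-(t - t_on)/tau)`` (zero before onset) over [a, b].

    Closed form of the window integral; checked against dense quadrature in
    the test suite.
    """
    lo = np.clip(t_on, a, b)
    with np.errstate(over="ignore"):
        integral = (b - lo) + tau * (np.exp(-(b - t_on) / tau) - np.exp(-(lo - t_on) / tau))
    integral = np.where(t_on >= b, 0.0, integral)
    return integral / (b - a)


def simulate_elution(truth: pd.DataFrame, cfg: ElutionConfig) -> QuantTable:
    """Noise-free filtration fold changes for one experiment.

    Returns a :class:`~mesosieve.quant.QuantTable` with one column per sampling
    window, named ``<experiment>|<label>``, and condition metadata carrying the
    pore size, dilution, window bounds and replicate id.  All values lie in
    [0, 1].
    """
    bad = (truth["class"] == "condensate") & (truth["lam"] <= 0)
    if bad.any():
        raise InvalidTruthError(
            f"condensate species with lam=0: {list(truth.index[bad][:5])}"
        )
    d_eff = effective_diameter(truth, cfg.dilution).to_numpy(float)
    ratio = d_eff / cfg.d_pore
    lam = truth["lam"].to_numpy(float)
    is_free = (truth["class"] == "free").to_numpy()
    passes = is_free | (ratio <= 1.0)
    deformable = (~passes) & (lam > 0)
    rigid = (~passes) & (lam <= 0)

    # rigid particles close to the cutoff pass partially (the membrane's pores
    # are polydisperse; d_pore is where retention becomes confident), decaying
    # to the leak floor far above the cutoff — time-independent, so rigid
    # species sit on the identity line of any two-window scatter
    rigid_fc = cfg.leak + (1.0 - cfg.leak) * np.exp(
        -np.maximum(ratio - 1.0, 0.0) / cfg.pore_width
    )
    values = np.empty((len(truth), len(cfg.windows)))
    for j, (a, b) in enumerate(cfg.windows):
        col = np.ones(len(truth))
        col[rigid] = rigid_fc[rigid]
        if deformable.any():
            r = ratio[deformable]
            lm = lam[deformable]
            t_on = np.minimum(1.0, cfg.beta * (r - 1.0) / lm)
            tau = cfg.tau0 * r / lm
            mean = _window_mean_after_onset(t_on, tau, a, b)
            # detection/leakage floor: heavily retained species are measured
            # at a small finite fold change, never exactly zero
            col[deformable] = np.maximum(mean, cfg.leak)
        values[:, j] = col

    columns = [f"{cfg.name}|{lab}" for lab in cfg.window_labels]
    conditions = pd.DataFrame(
        {
            "experiment": cfg.name,
            "pore_nm": cfg.d_pore,
            "dilution": cfg.dilution,
            "window_start": [w[0] for w in cfg.windows],
            "window_end": [w[1] for w in cfg.windows],
            "replicate": cfg.replicate,
        },
        index=pd.Index(columns, name="condition"),
    )
    frame = pd.DataFrame(values, index=truth.index.copy(), columns=columns)
    frame.index.name = "protein_id"
    return QuantTable(values=frame, conditions=conditions)


def add_measurement_noise(table: QuantTable, noise: NoiseConfig) -> QuantTable:
    """Multiply values by 2^eps (per cell) and 2^L (per condition column).

    ``eps ~ N(0, sigma_channel)``, ``L ~ N(0, sigma_loading)``.  Missing
    values are preserved; positivity is preserved by construction.
    """
    if (table.values < 0).any().any():
        raise InvalidInputError("fold changes must be >= 0 before noise")
    rng = _rng(noise.seed, _SALT_NOISE)
    eps = rng.normal(0.0, noise.sigma_channel, table.values.shape) if noise.sigma_channel else 0.0
    loading = (
        rng.normal(0.0, noise.sigma_loading, table.values.shape[1])
        if noise.sigma_loading
        else np.zeros(table.values.shape[1])
    )
    factors = np.exp2(eps + loading[np.newaxis, :])
    return QuantTable(
        values=table.values * factors,
        conditions=table.conditions.copy(),
        normalized=False,
    )


# ---------------------------------------------------------------------------
# sequence features and annotations
# ---------------------------------------------------------------------------

# Class-conditional feature parameters.  Condensate-class species carry the
# signatures of phase-separating proteins: high disorder, more/longer IDRs,
# nucleic-acid binding, glycine-rich / aliphatic-poor composition.
_IDR_BETA = {"condensate": (5.0, 2.7), "other": (2.0, 6.0)}
_RNA_P = {"condensate": 0.6, "other": 0.15}
_DNA_P = {"condensate": 0.3, "other": 0.08}
_COMPOSITION = {
    # column: (condensate mean, condensate sd, other mean, other sd)
    "frac_gly": (0.090, 0.015, 0.065, 0.010),
    "frac_cys": (0.012, 0.004, 0.023, 0.006),
    "frac_leu": (0.075, 0.010, 0.095, 0.010),
    "frac_ile": (0.040, 0.008, 0.055, 0.008),
    "frac_aliphatic": (0.22, 0.02, 0.28, 0.02),
    "frac_aromatic": (0.100, 0.015, 0.082, 0.012),
}


def generate_sequence_features(truth: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Class-correlated sequence features for every species.

    Columns: ``idr_frac`` (fraction of residues in intrinsically disordered
    regions), IDR counts (any length / >=30 aa / >=50 aa, nested so the
    counts are consistent), DNA/RNA-binding and RNA-binding-domain flags, and
    amino-acid composition fractions.  All fractions lie in [0, 1].
    """
    if truth.empty:
        raise InvalidInputError("truth table is empty")
    rng = _rng(seed, _SALT_FEATURES)
    n = len(truth)
    is_cond = (truth["class"] == "condensate").to_numpy()

    def _per_class(cond_val, other_val):
        return np.where(is_cond, cond_val, other_val)

    a = _per_class(_IDR_BETA["condensate"][0], _IDR_BETA["other"][0])
    b = _per_class(_IDR_BETA["condensate"][1], _IDR_BETA["other"][1])
    idr_frac = rng.beta(a, b)
    n_idr_any = rng.poisson(1.0 + 6.0 * idr_frac)
    n_idr_30 = rng.binomial(n_idr_any, 0.6)
    n_idr_50 = rng.binomial(n_idr_30, 0.5)
    rna = rng.random(n) < _per_class(_RNA_P["condensate"], _RNA_P["other"])
    dna = rng.random(n) < _per_class(_DNA_P["condensate"], _DNA_P["other"])
    rbd = rna & (rng.random(n) < 0.6)

    feats = {
        "idr_frac": idr_frac,
        "n_idr_any": n_idr_any,
        "n_idr_30": n_idr_30,
        "n_idr_50": n_idr_50,
        "dna_binding": dna.astype(int),
        "rna_binding": rna.astype(int),
        "rna_binding_domain": rbd.astype(int),
    }
    for col, (mc, sc, mo, so) in _COMPOSITION.items():
        vals = rng.normal(_per_class(mc, mo), _per_class(sc, so))
        feats[col] = np.clip(vals, 0.0, 1.0)
    out = pd.DataFrame(feats, index=truth.index.copy())
    out.index.name = "protein_id"
    return out


def generate_llps_database_memberships(
    truth: pd.DataFrame,
    features: pd.DataFrame,
    seed: int = 0,
    n_databases: int = 5,
) -> dict[str, list[str]]:
    """Simulate curated LLPS database id lists.

    Each of the ``n_databases`` sources independently lists a condensate
    species with probability increasing in its disorder content and
    RNA binding (stronger LLPS proteins are curated more often, so high
    consensus levels select the most canonical examples); non-condensate
    species appear only as rare curation noise.
    """
    rng = _rng(seed, _SALT_ANNOTATIONS)
    is_cond = (truth["class"] == "condensate").to_numpy()
    idr = features.loc[truth.index, "idr_frac"].to_numpy(float)
    rna = features.loc[truth.index, "rna_binding"].to_numpy(float)
    p = np.where(is_cond, np.clip(0.05 + 0.4 * idr + 0.1 * rna, 0, 1), 0.04)
    lists: dict[str, list[str]] = {}
    for k in range(n_databases):
        member = rng.random(len(truth)) < p
        lists[f"db{k + 1}"] = list(truth.index[member])
    return lists


def generate_annotations(
    truth: pd.DataFrame,
    features: pd.DataFrame,
    seed: int = 0,
    n_databases: int = 5,
) -> pd.DataFrame:
    """Reference annotation table for the simulated proteome.

    Boolean flags ``complex``, ``mitochondrion``, ``membrane_bound_organelle``,
    ``transmembrane``, ``rna_binding``, ``bmc_associated`` plus the integer
    ``llps_consensus`` column (number of simulated LLPS databases listing the
    protein, built through :func:`mesosieve.recall.merge_llps_references`).
    Complex and organelle flags mirror ground truth exactly — they stand for
    curated, reliable annotation; LLPS membership is deliberately noisy and
    incomplete, as curated LLPS databases are.
    """
    from .recall import merge_llps_references

    rng = _rng(seed, _SALT_ANNOTATIONS + 1)
    n = len(truth)
    is_complex = (truth["class"] == "complex").to_numpy()
    is_mbo = (truth["class"] == "membrane_organelle").to_numpy()
    is_cond = (truth["class"] == "condensate").to_numpy()
    ann = pd.DataFrame(index=truth.index.copy())
    ann.index.name = "protein_id"
    ann["complex"] = is_complex
    ann["membrane_bound_organelle"] = is_mbo
    ann["mitochondrion"] = is_mbo & (rng.random(n) < 0.5)
    ann["transmembrane"] = np.where(is_mbo, rng.random(n) < 0.8, rng.random(n) < 0.03)
    ann["rna_binding"] = features.loc[truth.index, "rna_binding"].astype(bool)
    ann["bmc_associated"] = np.where(is_cond, rng.random(n) < 0.3, rng.random(n) < 0.02)
    lists = generate_llps_database_memberships(truth, features, seed=seed, n_databases=n_databases)
    consensus = merge_llps_references(lists)
    ann["llps_consensus"] = consensus.reindex(ann.index).fillna(0).astype(int)
    return ann


# ---------------------------------------------------------------------------
# sedimentation and beads
# ---------------------------------------------------------------------------


def simulate_sedimentation(
    truth: pd.DataFrame,
    name: str = "sed",
    d_half: float = 150.0,
    floor: float = 0.02,
    replicate: int = 1,
) -> QuantTable:
    """Noise-free hard-spin assay: top vs bottom concentration per species.

    The sedimented mass fraction grows with assembly size,
    ``p = 1 - exp(-(d_eff/d_half)**3)``; the top half is depleted to
    ``max(1 - p, floor)`` and the bottom enriched to ``1 + p`` (mass
    conserving).  Free species stay at 1/1; organelles are strongly shifted.
    """
    d_eff = effective_diameter(truth, 1.0).to_numpy(float)
    p = 1.0 - np.exp(-((d_eff / d_half) ** 3))
    top = np.maximum(1.0 - p, floor)
    bottom = 1.0 + p
    columns = [f"{name}|top", f"{name}|bottom"]
    frame = pd.DataFrame({columns[0]: top, columns[1]: bottom}, index=truth.index.copy())
    frame.index.name = "protein_id"
    conditions = pd.DataFrame(
        {
            "experiment": name,
            "pore_nm": np.nan,
            "dilution": 1.0,
            "window_start": np.nan,
            "window_end": np.nan,
            "replicate": replicate,
        },
        index=pd.Index(columns, name="condition"),
    )
    return QuantTable(values=frame, conditions=conditions)


#: Bead cutoff sizes of the size-exclusion assay, nm.
DEFAULT_BEAD_CUTOFFS = (7.7, 15.0, 29.0, 53.0)


def simulate_bead_profiles(
    truth: pd.DataFrame,
    cutoffs: Sequence[float] = DEFAULT_BEAD_CUTOFFS,
    mono_weight: float = 0.15,
    seed: int = 0,
    rho0: float = 0.8,
    noise_cv: float = 0.0,
) -> pd.DataFrame:
    """Size-exclusion bead intensities and fill fractions per species.

    Each species carries a log-normal assembly-size distribution (location by
    class: free species sit below the smallest cutoff; complexes and
    organelles are narrowly peaked at their assembly size; condensates spread
    broadly across the mesoscale).  The fill fraction at cutoff ``s`` is
    ``mono_weight + (1 - mono_weight) * CDF(s)`` — a monomer/small-species
    weight plus the mass fraction of assemblies below the cutoff.  Simulated
    intensities follow ``I_in = fill * rho0 * I_out`` with optional
    multiplicative noise; dextran calibration rows (``is_calibration``) have
    ``I_in = rho0 * I_out``.
    """
    cutoffs = list(cutoffs)
    if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise InvalidConfigError(f"cutoffs must be strictly ascending, got {cutoffs}")
    if not (0 <= mono_weight <= 1):
        raise InvalidConfigError("mono_weight must be in [0, 1]")
    rng = _rng(seed, _SALT_BEADS)

    mu = np.empty(len(truth))
    sigma = np.empty(len(truth))
    cls = truth["class"].to_numpy()
    d0 = truth["d0"].to_numpy(float)
    mu[cls == "free"] = np.log(np.maximum(d0[cls == "free"], 1e-9))
    sigma[cls == "free"] = 0.35
    mu[cls == "complex"] = np.log(d0[cls == "complex"])
    sigma[cls == "complex"] = 0.2
    mu[cls == "condensate"] = np.log(d0[cls == "condensate"] / 3.0)
    sigma[cls == "condensate"] = 1.1
    mu[cls == "membrane_organelle"] = np.log(d0[cls == "membrane_organelle"])
    sigma[cls == "membrane_organelle"] = 0.3

    records: list[dict] = []
    i_out_base = 1000.0
    for s in cutoffs:
        cdf = norm.cdf((np.log(s) - mu) / sigma)
        fill = mono_weight + (1.0 - mono_weight) * cdf
        i_out = np.full(len(truth), i_out_base)
        i_in = fill * rho0 * i_out
        if noise_cv > 0:
            i_in = i_in * np.exp(rng.normal(0.0, noise_cv, len(truth)))
            i_out = i_out * np.exp(rng.normal(0.0, noise_cv, len(truth)))
        for k, sid in enumerate(truth.index):
            records.append(
                {
                    "species_id": sid,
                    "cutoff_nm": s,
                    "I_in": i_in[k],
                    "I_out": i_out[k],
                    "fill_true": fill[k],
                    "is_calibration": False,
                }
            )
        dex_out = i_out_base
        dex_in = rho0 * dex_out
        if noise_cv > 0:
            dex_in = dex_in * np.exp(rng.normal(0.0, noise_cv))
        records.append(
            {
                "species_id": "dextran",
                "cutoff_nm": s,
                "I_in": dex_in,
                "I_out": dex_out,
                "fill_true": np.nan,
                "is_calibration": True,
            }
        )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# scenario assembly used by the pipeline and tests
# ---------------------------------------------------------------------------


@dataclass
class FiltrationScenario:
    """The default multi-experiment study design on one simulated proteome.

    Per replicate: filtration chromatography at each pore size with an early
    (T1) and a late (T2) window, plus one dilution-series experiment at the
    mesoscale pore with a single mid-elution window per dilution factor.
    """

    truth: pd.DataFrame
    tables: list[QuantTable]

    @property
    def merged(self) -> QuantTable:
        from .quant import merge_quant_tables

        return merge_quant_tables(self.tables)


def simulate_filtration_scenario(
    truth: pd.DataFrame,
    pores: Sequence[float] = (30.0, 100.0, 200.0),
    dilutions: Sequence[float] = (1.2, 1.44, 2.0),
    dilution_pore: float = 100.0,
    replicates: int = 2,
    windows: Sequence[tuple[float, float]] = ((0.1, 0.3), (0.6, 0.9)),
    dilution_window: tuple[float, float] = (0.3, 0.7),
    noise: NoiseConfig | None = None,
    beta: float = 0.2,
    tau0: float = 0.15,
    leak: float = 0.02,
) -> FiltrationScenario:
    """Simulate the full filtration + dilution study on ``truth``.

    Returns one noisy :class:`QuantTable` per experiment (``filt<pore>_r<k>``
    with windows T1/T2; ``dil_r<k>`` with one column per dilution factor,
    including the undiluted reference ``f1.0``).  With ``noise=None`` the
    tables are noise-free.
    """
    from .quant import merge_quant_tables

    tables: list[QuantTable] = []
    noise_counter = 0
    for rep in range(1, replicates + 1):
        for pore in pores:
            cfg = ElutionConfig(
                name=f"filt{pore:g}_r{rep}",
                d_pore=pore,
                windows=windows,
                beta=beta,
                tau0=tau0,
                leak=leak,
                replicate=rep,
            )
            tables.append(simulate_elution(truth, cfg))
        dil_parts = []
        for f in (1.0, *dilutions):
            cfg = ElutionConfig(
                name=f"dil_r{rep}",
                d_pore=dilution_pore,
                windows=[dilution_window],
                labels=[f"f{f:g}"],
                dilution=f,
                beta=beta,
                tau0=tau0,
                leak=leak,
                replicate=rep,
            )
            dil_parts.append(simulate_elution(truth, cfg))
        tables.append(merge_quant_tables(dil_parts))
    if noise is not None:
        noisy = []
        for t in tables:
            noise_counter += 1
            noisy.append(
                add_measurement_noise(
                    t, replace(noise, seed=noise.seed + noise_counter)
                )
            )
        tables = noisy
    return FiltrationScenario(truth=truth, tables=tables)
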