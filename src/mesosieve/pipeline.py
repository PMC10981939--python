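"""One-command orchestration: simulate -> normalize -> score -> classify -> report.

Runs the whole analysis on a synthetic cytoplasm (or, stage by stage, on
user-supplied tables via the library API): filtration/dilution simulation with
measurement noise, per-experiment quantile normalization, replicate matching
and the empirical noise model, edge fit and squeezing scores with reference
recall, liquid-like behavior with FDR classification and proteome composition,
the bagged LLPS classifier, and the bead-profile metric.  Every output is a
TSV or JSON file; identical config + seed reproduces every byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .beads import bead_report
from .classifier import BagParams, assemble_features, combine_scores, crossval_scores
from .errors import InvalidConfigError
from .liquidity import (
    build_noise_model,
    fdr_classify,
    liquid_behavior,
    proteome_fractions,
)
from .quant import (
    QuantTable,
    match_replicates,
    merge_quant_tables,
    normalize_q95,
    write_quant_table,
)
from .recall import roc_auc
from .squeezing import fit_edge, squeezing_scores
from .synthetic import (
    DEFAULT_CLASS_FRACTIONS,
    NoiseConfig,
    generate_annotations,
    generate_proteome,
    generate_sequence_features,
    simulate_bead_profiles,
    simulate_filtration_scenario,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration of a full synthetic run.

    Either the simulator block (``n_species`` > 0) or input paths must be
    provided; the synthetic pipeline is the default.  All sizes and
    thresholds are ordinary config — the defaults are the study conditions.
    """

    seed: int = 7
    outdir: str = "sieve_out"
    # simulator block
    n_species: int = 4000
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    pores: Sequence[float] = (30.0, 100.0, 200.0)
    dilutions: Sequence[float] = (1.2, 1.44, 2.0)
    replicates: int = 2
    sigma_channel: float = 0.1
    sigma_loading: float = 0.1
    # or: paths to existing tables (quant + conditions + annotations)
    quant_path: str | None = None
    conditions_path: str | None = None
    # analysis block
    r_min: float = 0.8
    fdr: float = 0.02
    consensus_threshold: int = 4
    squeeze_experiment_pore: float = 30.0
    behavior_dilutions: Sequence[float] = (1.2, 1.44)
    behavior_pores: Sequence[float] = (30.0, 100.0)
    # classifier block
    n_ensembles: int = 600
    n_learners: int = 32
    class1_frac: float = 0.8
    class2_frac: float = 0.1
    # beads block
    n_bead_species: int = 24

    def validate(self) -> None:
        if self.n_species <= 0 and not (self.quant_path and self.conditions_path):
            raise InvalidConfigError(
                "config needs either a simulator block (n_species > 0) or "
                "input paths (quant_path, conditions_path)"
            )
        if not (0 < self.fdr < 1):
            raise InvalidConfigError(f"fdr must be in (0, 1), got {self.fdr}")
        if self.replicates < 1:
            raise InvalidConfigError("replicates must be >= 1")

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["class_fractions"] = dict(self.class_fractions)
        for key in ("pores", "dilutions", "behavior_dilutions", "behavior_pores"):
            out[key] = list(out[key])
        return out


def _config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", encoding="utf-8")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle to ``cfg.outdir``.

    Returns the summary dictionary (also written as ``summary.json``).
    Stage failures abort with the stage name; partial outputs are kept next
    to a FAILED marker naming the stage.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed}
    stage = "setup"
    try:
        # ------------------------------------------------------------- simulate
        stage = "simulate"
        logger.info("[simulate] generating %d species", cfg.n_species)
        truth = generate_proteome(
            cfg.n_species, cfg.class_fractions, seed=cfg.seed
        )
        features = generate_sequence_features(truth, seed=cfg.seed)
        annotations = generate_annotations(truth, features, seed=cfg.seed)
        noise = NoiseConfig(
            sigma_channel=cfg.sigma_channel,
            sigma_loading=cfg.sigma_loading,
            seed=cfg.seed,
        )
        scenario = simulate_filtration_scenario(
            truth,
            pores=cfg.pores,
            dilutions=cfg.dilutions,
            replicates=cfg.replicates,
            noise=noise,
        )
        truth.to_csv(outdir / "truth.tsv", sep="\t")
        features.to_csv(outdir / "features.tsv", sep="\t")
        annotations.to_csv(outdir / "annotations.tsv", sep="\t")

        # ------------------------------------------------------------ normalize
        stage = "normalize"
        tables = [normalize_q95(t) for t in scenario.tables]
        merged = merge_quant_tables(tables)
        write_quant_table(merged, outdir / "quant.tsv", outdir / "conditions.tsv")
        logger.info("[normalize] %d experiments, %d conditions", len(tables), merged.values.shape[1])

        # ----------------------------------------------------------- noise model
        stage = "noise_model"
        pairs = match_replicates(tables, r_min=cfg.r_min)
        noise_model = build_noise_model(pairs)
        summary["noise_model"] = {
            "n_pairs": noise_model.n_pairs,
            "n_residuals": int(len(noise_model.residuals)),
            "sd_log2": noise_model.sd,
        }

        # ------------------------------------------------------------- squeezing
        stage = "squeezing"
        squeeze_name = f"filt{cfg.squeeze_experiment_pore:g}_r1"
        x_late = merged.values[f"{squeeze_name}|T2"]
        y_early = merged.values[f"{squeeze_name}|T1"]
        lx, ly = np.log2(x_late), np.log2(y_early)
        edge = fit_edge(lx, ly)
        scores = squeezing_scores(lx, ly, edge)
        condensates = set(truth.index[truth["class"] == "condensate"])
        complexes = set(truth.index[truth["class"] == "complex"])
        roc_cond = roc_auc(scores, condensates)
        roc_comp = roc_auc(scores, complexes)
        score_frame = pd.DataFrame(
            {
                "score": scores.values,
                "used_in_edge": scores.values.index.isin(set(edge.support_ids)),
            }
        )
        score_frame.index.name = "protein_id"
        _write_tsv(score_frame, outdir / "squeezing_scores.tsv")
        pd.DataFrame({"fpr": roc_cond.fpr, "tpr": roc_cond.tpr}).to_csv(
            outdir / "roc_condensate.tsv", sep="\t", index=False
        )
        summary["squeezing"] = {
            "experiment": squeeze_name,
            "edge_slope": edge.slope,
            "edge_intercept": edge.intercept,
            "auc_condensate": roc_cond.auc,
            "auc_complex": roc_comp.auc,
        }
        logger.info(
            "[squeezing] edge %.3fx%+.3f, condensate AUC %.3f, complex AUC %.3f",
            edge.slope, edge.intercept, roc_cond.auc, roc_comp.auc,
        )

        # -------------------------------------------------------------- liquidity
        stage = "liquidity"
        scatters: dict[str, tuple[pd.Series, pd.Series]] = {}
        for rep in range(1, cfg.replicates + 1):
            for pore in cfg.behavior_pores:
                name = f"filt{pore:g}_r{rep}"
                scatters[name] = (
                    merged.values[f"{name}|T1"],
                    merged.values[f"{name}|T2"],
                )
            for f in cfg.behavior_dilutions:
                name = f"dil_r{rep}"
                scatters[f"{name}_f{f:g}"] = (
                    merged.values[f"{name}|f1"],
                    merged.values[f"{name}|f{f:g}"],
                )
        anchor_ids = set(
            annotations.index[annotations["complex"] | annotations["transmembrane"]]
        )
        behavior = liquid_behavior(scatters, anchor_ids)
        filt_cols = [
            f"filt{p:g}_r{rep}|{w}"
            for rep in range(1, cfg.replicates + 1)
            for p in cfg.behavior_pores
            for w in ("T1", "T2")
        ]
        filtration_log2 = np.log2(merged.values[filt_cols])
        membrane_ids = set(annotations.index[annotations["membrane_bound_organelle"]])
        behavior = fdr_classify(
            behavior,
            noise_model,
            fdr=cfg.fdr,
            membrane_ids=membrane_ids,
            filtration_log2=filtration_log2,
        )
        composition = proteome_fractions(behavior, annotations)
        _write_tsv(behavior.table, outdir / "liquidity.tsv")
        summary["liquidity"] = {
            "threshold": behavior.threshold,
            "small_bound": behavior.small_bound,
            "fractions": composition.fractions,
            "n_detected": composition.n_detected,
        }
        logger.info("[liquidity] fractions %s", composition.fractions)

        # -------------------------------------------------------------- classifier
        stage = "classifier"
        exp_conditions = [
            f"filt{p:g}_r1|{w}" for p in cfg.behavior_pores for w in ("T1", "T2")
        ] + [f"dil_r1|f{f:g}" for f in (1.0, *cfg.dilutions)]
        llps_ref = set(
            annotations.index[annotations["llps_consensus"] >= cfg.consensus_threshold]
        )
        X, y = assemble_features([merged], exp_conditions, features, llps_ref)
        params = BagParams(n_learners=cfg.n_learners)
        n_exp = len(exp_conditions)
        cv_exp = crossval_scores(
            X.iloc[:, :n_exp], y, cfg.n_ensembles, cfg.class1_frac, cfg.class2_frac,
            params=params, seed=cfg.seed + 1,
        )
        cv_seq = crossval_scores(
            X.iloc[:, n_exp:], y, cfg.n_ensembles, cfg.class1_frac, cfg.class2_frac,
            params=params, seed=cfg.seed + 2,
        )
        combined = combine_scores(cv_exp.scores, cv_seq.scores)
        out = pd.DataFrame(
            {
                "s_exp": cv_exp.scores,
                "s_seq": cv_seq.scores,
                "s_combined": combined.values,
                "n_eval": cv_exp.n_eval,
            }
        )
        out.index.name = "protein_id"
        _write_tsv(out, outdir / "classifier_scores.tsv")
        summary["classifier"] = {
            "n_class1": int(y.sum()),
            "n_proteins": int(len(y)),
            "auc_exp": roc_auc(cv_exp.scores.dropna(), llps_ref).auc,
            "auc_seq": roc_auc(cv_seq.scores.dropna(), llps_ref).auc,
            "auc_combined": roc_auc(combined.values.dropna(), llps_ref).auc,
        }
        logger.info("[classifier] %s", summary["classifier"])

        # ------------------------------------------------------------------ beads
        stage = "beads"
        subset_ids: list[str] = []
        for cls in ("free", "condensate"):
            ids = truth.index[truth["class"] == cls][: cfg.n_bead_species // 2]
            subset_ids.extend(ids)
        profiles = simulate_bead_profiles(truth.loc[subset_ids], seed=cfg.seed)
        report = bead_report(profiles)
        _write_tsv(report.set_index("species_id"), outdir / "beads.tsv")
        cv_by_class = (
            report.drop_duplicates("species_id")
            .join(truth["class"], on="species_id")
            .groupby("class")["step_cv"]
            .mean()
        )
        summary["beads"] = {f"mean_step_cv_{k}": float(v) for k, v in cv_by_class.items()}

        # ----------------------------------------------------------------- report
        stage = "report"
        manifest = {
            "config": cfg.to_dict(),
            "config_hash": _config_hash(cfg),
            "package_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
        )
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True), encoding="utf-8"
        )
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage={stage}\nerror={exc!r}\n", encoding="utf-8")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    marker = outdir / "FAILED"
    if marker.exists():
        marker.unlink()
    return summary
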