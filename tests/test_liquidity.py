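"""Noise model, liquid-like behavior, FDR classification and composition tests."""

import numpy as np
import pandas as pd
import pytest

from mesosieve import (
    LiquidBehavior,
    build_noise_model,
    fdr_classify,
    ks_two_sample,
    liquid_behavior,
    proteome_fractions,
)
from mesosieve.errors import InsufficientDataError, InvalidInputError
from mesosieve.quant import MatchedPair


def make_pair(x: np.ndarray, y: np.ndarray, name="p") -> MatchedPair:
    ids = [f"P{i}" for i in range(len(x))]
    return MatchedPair(
        0, f"{name}a", 1, f"{name}b", 0.99, len(x),
        pd.Series(x, index=ids), pd.Series(y, index=ids),
    )


class TestNoiseModel:
    def test_identical_replicates_zero_residuals(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(0, 1, 200)
        model = build_noise_model([make_pair(x, x.copy())])
        assert np.abs(model.residuals).max() < 1e-9

    def test_recovers_generating_sd(self):
        rng = np.random.default_rng(1)
        x = np.exp2(rng.normal(0, 2, 1000))
        y = x * np.exp2(rng.normal(0, 0.2, 1000))
        model = build_noise_model([make_pair(x, y)])
        assert abs(model.sd - 0.2) / 0.2 < 0.10

    def test_pooling_counts(self):
        rng = np.random.default_rng(2)
        pairs = [
            make_pair(rng.lognormal(0, 1, 100), rng.lognormal(0, 1, 100), "a"),
            make_pair(rng.lognormal(0, 1, 150), rng.lognormal(0, 1, 150), "b"),
        ]
        model = build_noise_model(pairs)
        assert len(model.residuals) == 250
        assert model.n_pairs == 2

    def test_zero_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            build_noise_model([])


def two_cluster_scatter(rng, n_anchor=60, n_liquid=40, shift=2.0):
    """Anchors spread along the identity in FC space; liquid species shifted up."""
    ids_a = [f"A{i}" for i in range(n_anchor)]
    ids_l = [f"L{i}" for i in range(n_liquid)]
    xa = np.exp2(rng.uniform(-6, 0, n_anchor))
    xl = np.exp2(rng.uniform(-5, -1, n_liquid))
    x = pd.Series(np.r_[xa, xl], index=ids_a + ids_l)
    y = pd.Series(np.r_[xa, xl * 2.0**shift], index=ids_a + ids_l)
    return x, y, ids_a, ids_l


class TestLiquidBehavior:
    def test_anchor_mean_behavior_is_zero(self):
        rng = np.random.default_rng(3)
        x, y, anchors, _ = two_cluster_scatter(rng)
        lb = liquid_behavior({"e1": (x, y)}, anchors)
        assert abs(lb.table.loc[anchors, "behavior"].mean()) < 1e-9

    def test_liquid_species_shifted_up(self):
        rng = np.random.default_rng(4)
        x, y, anchors, liquid = two_cluster_scatter(rng, shift=2.0)
        lb = liquid_behavior({"e1": (x, y)}, anchors)
        assert lb.table.loc[liquid, "behavior"].min() > 1.5

    def test_single_experiment_protein(self):
        rng = np.random.default_rng(5)
        x1, y1, anchors, _ = two_cluster_scatter(rng)
        x2, y2, _, _ = two_cluster_scatter(rng)
        x2 = x2.drop("L0")
        y2 = y2.drop("L0")
        lb = liquid_behavior({"e1": (x1, y1), "e2": (x2, y2)}, anchors)
        assert lb.table.loc["L0", "n_used"] == 1
        assert lb.table.loc["L0", "behavior"] == pytest.approx(
            lb.per_experiment.loc["L0", "e1"]
        )

    def test_empty_anchor_set_rejected(self):
        rng = np.random.default_rng(6)
        x, y, _, _ = two_cluster_scatter(rng)
        with pytest.raises(InvalidInputError):
            liquid_behavior({"e1": (x, y)}, [])

    def test_simulated_condensates_separate_from_complexes(self, truth, study, annotations):
        merged = study["merged"]
        scatters = {
            f"filt{p}_r1": (merged.values[f"filt{p}_r1|T1"], merged.values[f"filt{p}_r1|T2"])
            for p in (30, 100)
        }
        anchors = set(annotations.index[annotations["complex"] | annotations["transmembrane"]])
        lb = liquid_behavior(scatters, anchors)
        b = lb.table["behavior"]
        cond = b[truth.index[truth["class"] == "condensate"]].dropna()
        comp = b[truth.index[truth["class"] == "complex"]].dropna()
        _, p = ks_two_sample(cond.to_numpy(), comp.to_numpy())
        assert p < 1e-6
        assert cond.median() > comp.median()


def null_behavior_table(values, ids=None):
    ids = ids or [f"N{i}" for i in range(len(values))]
    table = pd.DataFrame({"behavior": values, "n_used": 1}, index=pd.Index(ids, name="protein_id"))
    return LiquidBehavior(table=table, anchor_ids=frozenset(), per_experiment=pd.DataFrame())


@pytest.fixture(scope="module")
def noise_model():
    rng = np.random.default_rng(7)
    x = np.exp2(rng.normal(0, 2, 2000))
    y = x * np.exp2(rng.normal(0, 0.15, 2000))
    return build_noise_model([make_pair(x, y)])


class TestFdrClassify:
    def test_extreme_outlier_flagged(self, noise_model):
        # the +1 tail pseudo-count bounds the estimate below by N/(n_null+1),
        # so a lone outlier is only detectable when the pooled null is much
        # larger than the cohort — as it is in practice (replicate pairs
        # contribute one residual per protein each)
        rng = np.random.default_rng(8)
        vals = np.r_[noise_model.sample(30, rng), [10 * noise_model.sd]]
        out = fdr_classify(null_behavior_table(vals), noise_model)
        assert bool(out.table["bmc_positive"].iloc[-1])

    def test_vacuous_fdr_flags_every_non_membrane(self, noise_model):
        rng = np.random.default_rng(9)
        vals = noise_model.sample(200, rng)
        lb = null_behavior_table(vals)
        out = fdr_classify(lb, noise_model, fdr=1.0, membrane_ids={"N0", "N1"})
        flags = out.table["bmc_positive"]
        assert not flags.loc[["N0", "N1"]].any()
        assert flags.drop(["N0", "N1"]).all()

    def test_null_draws_rarely_flagged(self, noise_model):
        total_flagged = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            out = fdr_classify(null_behavior_table(noise_model.sample(1000, rng)), noise_model)
            total_flagged += int(out.table["bmc_positive"].sum())
        assert total_flagged <= 0.02 * 10 * 1000

    def test_positive_sets_nest_with_fdr(self, noise_model):
        rng = np.random.default_rng(10)
        vals = np.r_[noise_model.sample(900, rng), rng.normal(1.5, 0.3, 100)]
        lb = null_behavior_table(vals)
        previous = None
        for fdr in (0.10, 0.05, 0.02, 0.01):
            out = fdr_classify(lb, noise_model, fdr=fdr)
            positives = set(out.table.index[out.table["bmc_positive"]])
            if previous is not None:
                assert positives <= previous
            previous = positives

    def test_tail_method_thresholds_at_null_quantile(self, noise_model):
        rng = np.random.default_rng(13)
        vals = noise_model.sample(400, rng)
        out = fdr_classify(null_behavior_table(vals), noise_model, fdr=0.02, method="tail")
        expected = np.quantile(noise_model.residuals - noise_model.median, 0.98)
        assert out.threshold == pytest.approx(expected)
        # per-comparison tail thresholding flags ~2% of pure-null proteins
        rate = out.table["bmc_positive"].mean()
        assert rate == pytest.approx(0.02, abs=3 * np.sqrt(0.02 * 0.98 / 400))
        with pytest.raises(InvalidInputError):
            fdr_classify(null_behavior_table(vals), noise_model, method="bogus")

    def test_small_flag_uses_two_sided_bound(self, noise_model):
        vals = noise_model.sample(50, np.random.default_rng(11))
        lb = null_behavior_table(vals)
        bound = noise_model.two_sided_bound(0.02)
        filt = pd.DataFrame(
            {"f1": np.r_[np.zeros(25), np.full(25, -5.0)]},
            index=lb.table.index,
        )
        out = fdr_classify(lb, noise_model, filtration_log2=filt)
        assert out.small_bound == pytest.approx(bound)
        assert out.table["small"].iloc[:25].all()
        assert not out.table["small"].iloc[25:].any()


class TestProteomeFractions:
    def test_all_membrane_degenerate(self, noise_model):
        lb = fdr_classify(
            null_behavior_table(np.zeros(10)), noise_model, membrane_ids={f"N{i}" for i in range(10)}
        )
        ann = pd.DataFrame(
            {"membrane_bound_organelle": True}, index=[f"N{i}" for i in range(10)]
        )
        report = proteome_fractions(lb, ann)
        assert report.fractions["membrane_bound_organelle"] == 1.0
        assert report.fractions["bmc"] == 0.0

    def test_fractions_sum_to_one(self, noise_model):
        rng = np.random.default_rng(12)
        vals = np.r_[noise_model.sample(300, rng), rng.normal(2, 0.2, 100)]
        lb = fdr_classify(
            null_behavior_table(vals), noise_model, membrane_ids={f"N{i}" for i in range(50)}
        )
        ann = pd.DataFrame(
            {"membrane_bound_organelle": [i < 50 for i in range(400)]},
            index=[f"N{i}" for i in range(400)],
        )
        report = proteome_fractions(lb, ann)
        assert sum(report.fractions.values()) == pytest.approx(1.0, abs=1e-12)
        assert sum(len(v) for v in report.members.values()) == 400

    def test_flags_required(self):
        lb = null_behavior_table(np.zeros(5))
        with pytest.raises(InvalidInputError):
            proteome_fractions(lb, pd.DataFrame({"membrane_bound_organelle": []}))
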