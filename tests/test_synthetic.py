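"""Simulator unit tests: ground truth, elution physics, noise, features, beads."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from mesosieve import (
    ElutionConfig,
    NoiseConfig,
    add_measurement_noise,
    effective_diameter,
    generate_proteome,
    generate_sequence_features,
    simulate_bead_profiles,
    simulate_elution,
    simulate_sedimentation,
)
from mesosieve.errors import (
    InvalidConfigError,
    InvalidInputError,
    InvalidTruthError,
)

from conftest import single_condensate, species_row


class TestGenerateProteome:
    def test_empty_proteome(self):
        table = generate_proteome(0, {"free": 0.5, "condensate": 0.5})
        assert len(table) == 0

    def test_multinomial_class_counts(self):
        n = 4000
        table = generate_proteome(n, {"free": 0.5, "condensate": 0.5}, seed=11)
        n_cond = int((table["class"] == "condensate").sum())
        assert abs(n_cond - 2000) <= 3 * np.sqrt(n * 0.25)

    def test_seed_reproducibility(self):
        a = generate_proteome(500, seed=3)
        b = generate_proteome(500, seed=3)
        pd.testing.assert_frame_equal(a, b)
        c = generate_proteome(500, seed=4)
        assert not a["d0"].equals(c["d0"])

    def test_invariants(self):
        table = generate_proteome(2000, seed=5)
        assert (table["d0"] >= table["d_mono"]).all()
        assert (table["d_mono"] > 0).all()
        free = table[table["class"] == "free"]
        assert (free["d0"] == free["d_mono"]).all()
        rigid = table[table["class"].isin(["complex", "membrane_organelle"])]
        assert (rigid["lam"] == 0).all()
        cond = table[table["class"] == "condensate"]
        assert cond["phi_core"].between(0, 1).all()
        assert ((cond["lam"] > 0) & (cond["lam"] <= 1)).all()

    def test_bad_fractions_rejected(self):
        with pytest.raises(InvalidConfigError):
            generate_proteome(10, {"free": 0.6, "condensate": 0.5})
        with pytest.raises(InvalidConfigError):
            generate_proteome(10, {"free": 0.5, "martian": 0.5})

    def test_negative_n_rejected(self):
        with pytest.raises(InvalidInputError):
            generate_proteome(-1)


class TestEffectiveDiameter:
    def test_free_species_unaffected(self):
        truth = species_row("free", d0=5.0)
        for f in (1.0, 2.0, 8.0):
            assert effective_diameter(truth, f).iloc[0] == 5.0

    def test_solid_core_blocks_dissolution(self):
        truth = single_condensate(d0=100.0, phi_core=1.0, c_ratio=2.0)
        assert effective_diameter(truth, 8.0).iloc[0] == pytest.approx(100.0)

    def test_cube_root_shrinkage(self):
        # phi(1) = 1 - 1/2 = 0.5; phi(1.5) = 1 - 1.5/2 = 0.25
        truth = single_condensate(d0=100.0, phi_core=0.0, c_ratio=2.0)
        expected = 100.0 * (0.25 / 0.5) ** (1.0 / 3.0)
        assert effective_diameter(truth, 1.5).iloc[0] == pytest.approx(expected, rel=1e-12)
        # approaching full dissolution the diameter collapses to the monomer
        assert effective_diameter(truth, 2.0).iloc[0] == pytest.approx(5.0)

    def test_dilution_below_one_rejected(self):
        with pytest.raises(InvalidInputError):
            effective_diameter(single_condensate(), 0.5)


class TestSimulateElution:
    def test_free_species_pass_freely(self):
        truth = species_row("free", d0=5.0)
        cfg = ElutionConfig("e", d_pore=30.0, windows=[(0.0, 0.2), (0.5, 1.0)])
        table = simulate_elution(truth, cfg)
        assert (table.values.to_numpy() == 1.0).all()

    def test_rigid_far_above_cutoff_at_leak(self):
        truth = species_row("membrane_organelle", d0=300.0)
        cfg = ElutionConfig("e", d_pore=30.0, windows=[(0.0, 0.3), (0.6, 0.9)], leak=0.02)
        table = simulate_elution(truth, cfg)
        assert table.values.to_numpy() == pytest.approx(0.02, abs=1e-12)

    def test_deformable_window_mean_closed_form(self):
        # t_on = 0.3, tau = 0.2, window [0.3, 0.5]: mean of 1 - exp(-(t-0.3)/0.2)
        # over one time constant equals exp(-1)
        truth = single_condensate(d0=100.0, lam=1.0, c_ratio=50.0)
        cfg = ElutionConfig(
            "e", d_pore=40.0, windows=[(0.3, 0.5)], beta=0.2, tau0=0.08, leak=0.0
        )
        table = simulate_elution(truth, cfg)
        assert table.values.iloc[0, 0] == pytest.approx(np.exp(-1), rel=1e-9)

    @pytest.mark.parametrize("window", [(0.0, 0.25), (0.2, 0.4), (0.35, 0.9), (0.9, 1.0)])
    def test_window_mean_matches_quadrature(self, window):
        truth = single_condensate(d0=120.0, lam=0.8, c_ratio=50.0)
        cfg = ElutionConfig("e", d_pore=40.0, windows=[window], beta=0.2, tau0=0.15, leak=0.0)
        r = 3.0
        t_on = min(1.0, 0.2 * (r - 1.0) / 0.8)
        tau = 0.15 * r / 0.8
        fc = lambda t: 0.0 if t < t_on else 1.0 - np.exp(-(t - t_on) / tau)
        a, b = window
        oracle = quad(fc, a, b, points=[t_on] if a < t_on < b else None, limit=200)[0] / (b - a)
        assert simulate_elution(truth, cfg).values.iloc[0, 0] == pytest.approx(oracle, abs=1e-6)

    def test_condensate_without_deformability_rejected(self):
        truth = single_condensate(lam=0.0)
        truth.loc[:, "lam"] = 0.0
        cfg = ElutionConfig("e", d_pore=30.0, windows=[(0.0, 1.0)])
        with pytest.raises(InvalidTruthError):
            simulate_elution(truth, cfg)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(InvalidConfigError):
            ElutionConfig("e", d_pore=30.0, windows=[(0.0, 0.5), (0.4, 0.8)])

    def test_later_window_elutes_at_least_as_much(self):
        truth = generate_proteome(300, seed=2)
        cfg = ElutionConfig("e", d_pore=30.0, windows=[(0.1, 0.3), (0.6, 0.9)])
        vals = simulate_elution(truth, cfg).values
        assert ((vals.iloc[:, 1] - vals.iloc[:, 0]) >= -1e-12).all()
        assert vals.to_numpy().min() >= 0.0 and vals.to_numpy().max() <= 1.0


class TestMeasurementNoise:
    def test_zero_noise_is_identity(self):
        truth = generate_proteome(100, seed=1)
        table = simulate_elution(truth, ElutionConfig("e", 30.0, [(0.1, 0.4)]))
        noisy = add_measurement_noise(table, NoiseConfig(0.0, 0.0, seed=0))
        pd.testing.assert_frame_equal(noisy.values, table.values)

    def test_loading_noise_is_column_wise(self):
        truth = generate_proteome(50, seed=1)
        table = simulate_elution(truth, ElutionConfig("e", 30.0, [(0.1, 0.4), (0.5, 0.9)]))
        noisy = add_measurement_noise(table, NoiseConfig(0.0, 1.0, seed=0))
        factors = noisy.values / table.values
        for col in factors.columns:
            assert factors[col].std() == pytest.approx(0.0, abs=1e-12)
        assert factors.iloc[0, 0] != pytest.approx(factors.iloc[0, 1])

    def test_channel_noise_moments(self):
        values = pd.DataFrame(
            np.ones((10000, 1)),
            index=[f"P{i}" for i in range(10000)],
            columns=["e|T1"],
        )
        conditions = pd.DataFrame(
            {"experiment": ["e"], "pore_nm": [30.0], "dilution": [1.0],
             "window_start": [0.0], "window_end": [1.0], "replicate": [1]},
            index=pd.Index(["e|T1"], name="condition"),
        )
        from mesosieve import QuantTable

        table = QuantTable(values=values, conditions=conditions)
        noisy = add_measurement_noise(table, NoiseConfig(0.1, 0.0, seed=3))
        sd = np.log2(noisy.values.to_numpy()).std()
        assert abs(sd - 0.1) / 0.1 < 0.05


class TestSequenceFeatures:
    def test_condensates_are_more_disordered(self):
        free = generate_proteome(400, {"free": 1.0}, seed=2)
        cond = generate_proteome(400, {"condensate": 1.0}, seed=2)
        f_free = generate_sequence_features(free, seed=2)
        f_cond = generate_sequence_features(cond, seed=2)
        assert f_cond["idr_frac"].mean() > f_free["idr_frac"].mean()
        assert f_cond["frac_gly"].mean() > f_free["frac_gly"].mean()
        assert f_cond["frac_leu"].mean() < f_free["frac_leu"].mean()

    def test_reproducible_and_bounded(self):
        truth = generate_proteome(300, seed=4)
        a = generate_sequence_features(truth, seed=9)
        b = generate_sequence_features(truth, seed=9)
        pd.testing.assert_frame_equal(a, b)
        frac_cols = [c for c in a.columns if c.startswith("frac") or c == "idr_frac"]
        assert a[frac_cols].to_numpy().min() >= 0.0
        assert a[frac_cols].to_numpy().max() <= 1.0
        assert (a["n_idr_any"] >= a["n_idr_30"]).all()
        assert (a["n_idr_30"] >= a["n_idr_50"]).all()

    def test_rna_binding_rate(self):
        truth = generate_proteome(5000, {"condensate": 1.0}, seed=6)
        feats = generate_sequence_features(truth, seed=6)
        rate = feats["rna_binding"].mean()
        assert abs(rate - 0.6) <= 3 * np.sqrt(0.6 * 0.4 / 5000)

    def test_empty_truth_rejected(self):
        with pytest.raises(InvalidInputError):
            generate_sequence_features(generate_proteome(0))


class TestBeadProfiles:
    def test_all_monomeric_fills_everywhere(self):
        truth = generate_proteome(20, seed=1)
        prof = simulate_bead_profiles(truth, mono_weight=1.0)
        data = prof[~prof["is_calibration"]]
        assert data["fill_true"].to_numpy() == pytest.approx(1.0)

    def test_condensate_profile_strictly_increases(self):
        truth = single_condensate(d0=100.0)
        prof = simulate_bead_profiles(truth, mono_weight=0.15)
        fills = prof[~prof["is_calibration"]].sort_values("cutoff_nm")["fill_true"].to_numpy()
        assert (np.diff(fills) > 0).all()

    def test_fill_approaches_one_at_large_cutoff(self):
        truth = single_condensate(d0=100.0)
        prof = simulate_bead_profiles(truth, cutoffs=[10.0, 1e7])
        last = prof[~prof["is_calibration"]].sort_values("cutoff_nm")["fill_true"].iloc[-1]
        assert last == pytest.approx(1.0, abs=1e-9)

    def test_non_ascending_cutoffs_rejected(self):
        with pytest.raises(InvalidConfigError):
            simulate_bead_profiles(single_condensate(), cutoffs=[15.0, 7.7])


def test_sedimentation_depletes_large_assemblies():
    truth = pd.concat(
        [species_row("membrane_organelle", 500.0, sid="M"), species_row("free", 5.0, sid="F")]
    )
    table = simulate_sedimentation(truth)
    assert table.values.loc["M", "sed|top"] < 0.1
    assert table.values.loc["F", "sed|top"] == pytest.approx(1.0, abs=1e-3)
    assert table.values.loc["F", "sed|bottom"] == pytest.approx(1.0, abs=1e-3)
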