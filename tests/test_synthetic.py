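"""Ground-truth generators: contracts, determinism and closed-form checks."""

import numpy as np
import pandas as pd
import pytest

from nucitox import pipeline
from nucitox.synthetic import (
    DrugEffectSpec,
    FieldGenerationError,
    FieldSpec,
    PlateConfig,
    generate_dynamics,
    generate_field,
    generate_reporter_intensities,
    generate_viability_plate,
)


class TestDrugEffectSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            DrugEffectSpec("x", ic50_true=-1.0)
        with pytest.raises(ValueError):
            DrugEffectSpec("x", ic50_true=1.0, hill=0.0)
        with pytest.raises(ValueError):
            DrugEffectSpec("x", ic50_true=1.0, metabolic_factor_phi=-0.1)

    def test_viability_is_logistic_at_full_emax(self):
        d = DrugEffectSpec("x", ic50_true=2.0, hill=1.5)
        c = np.array([0.5, 2.0, 8.0])
        assert d.viability(c) == pytest.approx(1 / (1 + (c / 2.0) ** 1.5))
        assert d.viability(2.0) == pytest.approx(0.5)

    def test_emax_floor(self):
        d = DrugEffectSpec("x", ic50_true=1.0, emax=0.6)
        assert d.viability(1e9) == pytest.approx(0.4, abs=1e-6)


class TestViabilityPlate:
    def test_no_bias_makes_xtt_match_hoechst(self, noise_free_plate_cfg):
        drugs = [DrugEffectSpec("d", ic50_true=1.0, hill=1.2)]  # phi == 1
        plate = generate_viability_plate(noise_free_plate_cfg, drugs)
        v = pipeline.plate_viability(plate)
        piv = v.pivot_table(index="conc_uM", columns="method", values="viability_pct")
        assert piv["XTT"].to_numpy() == pytest.approx(piv["Hoechst"].to_numpy(), abs=1e-9)

    def test_constant_phi_doubles_xtt_viability(self, noise_free_plate_cfg):
        cfg = PlateConfig(**{**noise_free_plate_cfg.__dict__, "phi_toxic_only": False})
        drugs = [DrugEffectSpec("d", ic50_true=1.0, hill=1.2, metabolic_factor_phi=2.0)]
        plate = generate_viability_plate(cfg, drugs)
        v = pipeline.plate_viability(plate)
        piv = v.pivot_table(index="conc_uM", columns="method", values="viability_pct")
        assert piv["XTT"].to_numpy() == pytest.approx(2.0 * piv["Hoechst"].to_numpy())
        below_100 = piv["Hoechst"] < 100
        assert (piv.loc[below_100, "XTT"] > piv.loc[below_100, "Hoechst"]).all()

    def test_same_seed_gives_byte_identical_csv(self):
        cfg = PlateConfig(seed=42)
        drugs = [DrugEffectSpec("d", ic50_true=0.7, hill=1.0)]
        a = generate_viability_plate(cfg, drugs).to_csv(index=False)
        b = generate_viability_plate(cfg, drugs).to_csv(index=False)
        assert a == b

    def test_h2b_thinned_by_transduction(self, noise_free_plate_cfg):
        plate = generate_viability_plate(
            noise_free_plate_cfg, [DrugEffectSpec("d", ic50_true=1.0)]
        )
        h2b = plate[(plate.method == "H2B") & (plate.conc_uM == 0)]["value"].mean()
        hoechst = plate[(plate.method == "Hoechst") & (plate.conc_uM == 0)]["value"].mean()
        assert h2b == pytest.approx(0.95 * hoechst)

    def test_ground_truth_columns_present(self, noise_free_plate_cfg):
        plate = generate_viability_plate(noise_free_plate_cfg, [DrugEffectSpec("d", ic50_true=1.0)])
        assert {"true_cells", "true_viability"} <= set(plate.columns)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PlateConfig(methods=())
        with pytest.raises(ValueError):
            PlateConfig(concentrations=(1.0, 0.5, 2.0))
        with pytest.raises(ValueError):
            PlateConfig(transduction_fraction={"H1299": 1.4})
        cfg = PlateConfig()
        with pytest.raises(ValueError):
            generate_viability_plate(cfg, [])

    def test_noise_free_plate_recovers_true_ic50(self, noise_free_plate_cfg):
        """End-to-end normalization recovery: IC50 within 0.1% for every drug."""
        drugs = [
            DrugEffectSpec("a", ic50_true=0.4, hill=0.8),
            DrugEffectSpec("b", ic50_true=3.0, hill=1.7),
        ]
        plate = generate_viability_plate(noise_free_plate_cfg, drugs)
        metrics = pipeline.dose_metrics_table(pipeline.plate_viability(plate))
        for d in drugs:
            fits = metrics[metrics.drug == d.name]
            assert (abs(fits["ic50_uM"] - d.ic50_true) / d.ic50_true < 1e-3).all()


class TestFields:
    def test_empty_field_is_background_only(self, neutral_effect):
        spec = FieldSpec(height=64, width=64, n_cells=0, photon_noise_sd=0.0, seed=1)
        fd = generate_field(spec, neutral_effect)
        assert fd.cell_mask.max() == 0 and fd.nucleus_mask.max() == 0
        assert np.allclose(fd.channels["nuclei"], np.round(fd.background))

    def test_requested_cell_count_by_construction(self, small_field):
        spec, fd = small_field
        assert len(np.unique(fd.nucleus_mask)) - 1 == spec.n_cells
        assert len(fd.truth) == spec.n_cells

    def test_mito_factor_scales_truth_exactly(self):
        spec = FieldSpec(height=256, width=256, n_cells=8, seed=13)
        base = generate_field(spec, DrugEffectSpec("a", ic50_true=1.0, mito_activity_factor=1.0))
        boosted = generate_field(spec, DrugEffectSpec("a", ic50_true=1.0, mito_activity_factor=2.0))
        ratio = (
            boosted.truth["integrated_mito_intensity"] / base.truth["integrated_mito_intensity"]
        )
        assert ratio.to_numpy() == pytest.approx(np.full(8, 2.0))

    def test_truth_conserves_mito_intensity(self, small_field):
        _, fd = small_field
        per_cell = fd.truth["integrated_mito_intensity"].sum()
        per_px = (
            fd.truth["mito_intensity_per_px"].iloc[0] * (fd.mito_mask > 0).sum()
        )
        assert per_cell == per_px

    def test_unplaceable_field_raises(self, neutral_effect):
        spec = FieldSpec(height=64, width=64, n_cells=50, seed=1)
        with pytest.raises(FieldGenerationError):
            generate_field(spec, neutral_effect)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            FieldSpec(mito_fraction=0.0)
        with pytest.raises(ValueError):
            FieldSpec(cell_diameter_small=-3)


class TestDynamics:
    def _cfg(self):
        return PlateConfig(noise_cv=0.0, replicates=2, seed=3)

    def test_no_rates_flat_series(self):
        effect = DrugEffectSpec("d", ic50_true=1.0)
        dyn = generate_dynamics(self._cfg(), effect, [0, 24, 48, 72])
        assert dyn.groupby("time_h")["count"].std().fillna(0).eq(0).all()
        assert dyn["count"].nunique() == 1

    def test_doubling_time_closed_form(self):
        effect = DrugEffectSpec("d", ic50_true=1.0, growth_rate=np.log(2) / 24)
        dyn = generate_dynamics(self._cfg(), effect, [0, 24, 48, 72])
        ctrl = dyn[(dyn.conc_uM == 0) & (dyn.replicate == 1)].sort_values("time_h")
        assert ctrl["count"].to_numpy() == pytest.approx(
            ctrl["count"].iloc[0] * 2.0 ** np.arange(4)
        )

    def test_dominant_kill_rate_decreasing_at_saturation(self):
        effect = DrugEffectSpec("d", ic50_true=0.01, growth_rate=0.01, kill_rate=0.05)
        dyn = generate_dynamics(self._cfg(), effect, [0, 24, 48])
        high_c = dyn[(dyn.conc_uM == dyn.conc_uM.max()) & (dyn.replicate == 1)]
        counts = high_c.sort_values("time_h")["count"].to_numpy()
        assert np.all(np.diff(counts) < 0)

    def test_timepoint_validation(self):
        effect = DrugEffectSpec("d", ic50_true=1.0)
        with pytest.raises(ValueError):
            generate_dynamics(self._cfg(), effect, [-1, 0, 24])
        with pytest.raises(ValueError):
            generate_dynamics(self._cfg(), effect, [24, 48])


class TestReporterSamples:
    def test_null_shift_same_distribution(self):
        cfg = PlateConfig(seed=5)
        a = generate_reporter_intensities(cfg, DrugEffectSpec("x", ic50_true=1.0), 4, 50)
        b = generate_reporter_intensities(
            cfg, DrugEffectSpec("x", ic50_true=1.0, reporter_shift=1.0), 4, 50
        )
        assert a["median_intensity"].to_numpy() == pytest.approx(b["median_intensity"].to_numpy())

    def test_noise_free_shift_is_exact_median_ratio(self):
        cfg = PlateConfig(seed=5)
        kw = dict(nucleus_sigma=0.0, image_sigma=0.0)
        ctrl = generate_reporter_intensities(cfg, DrugEffectSpec("c", ic50_true=1.0), 3, 20, **kw)
        drug = generate_reporter_intensities(
            cfg, DrugEffectSpec("d", ic50_true=1.0, reporter_shift=1.5), 3, 20, **kw
        )
        ratio = drug["median_intensity"].median() / ctrl["median_intensity"].median()
        assert ratio == pytest.approx(1.5)

    def test_seeded_reproducibility(self):
        cfg = PlateConfig(seed=9)
        d = DrugEffectSpec("d", ic50_true=1.0, reporter_shift=1.2)
        a = generate_reporter_intensities(cfg, d, 5, 30)
        b = generate_reporter_intensities(cfg, d, 5, 30)
        pd.testing.assert_frame_equal(a, b)

    def test_argument_validation(self):
        cfg = PlateConfig(seed=1)
        d = DrugEffectSpec("d", ic50_true=1.0)
        with pytest.raises(ValueError):
            generate_reporter_intensities(cfg, d, 0, 10)
        with pytest.raises(ValueError):
            generate_reporter_intensities(cfg, d, 3, 0)
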