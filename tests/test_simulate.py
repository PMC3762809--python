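"""Synthetic seasonal core generator and forward measurement model."""

import numpy as np
import pandas as pd
import pytest

from sednitrate import ValidationError
from sednitrate.correlate import spearman_rho
from sednitrate.metrics import DEFAULT_FUCO_THRESHOLD
from sednitrate.partition import partition_table
from sednitrate.pipeline import areal_table, slice_metrics
from sednitrate.simulate import (
    SimulationParams,
    forward_measurement,
    simulate_dataset,
    simulate_truth,
)


class TestParams:
    def test_invalid_porosity_rejected_before_sampling(self):
        with pytest.raises(ValidationError, match="porosity"):
            simulate_truth(SimulationParams(porosity=1.2))

    def test_ratio_endpoints_ordered(self):
        with pytest.raises(ValidationError):
            SimulationParams(fuco_chl_surface=0.2, fuco_chl_deep=0.8).validate()


class TestSimulateTruth:
    def test_determinism(self, default_params):
        a = simulate_truth(default_params)
        b = simulate_truth(default_params)
        pd.testing.assert_frame_equal(a, b)

    def test_design_shape(self, default_params):
        t = simulate_truth(default_params)
        assert len(t) == 12 * 3 * 10
        assert t["month"].nunique() == 12

    def test_zero_enrichment_means_no_icno3(self, default_params):
        t = simulate_truth(default_params.replace(enrichment=0.0))
        assert (t["icno3_sed"] == 0).all()

    def test_seasonal_antiphase(self, default_params):
        p = default_params
        months = np.arange(1, 13)
        rho = spearman_rho(p.temperature(months), p.owno3(months))
        assert rho < 0

    def test_enrichment_exact_before_noise(self, default_params):
        p = default_params.replace(noise_cv=0.0)
        t = simulate_truth(p)
        mid = t["top_cm"].to_numpy() + 0.5
        pw_conc = t["pwno3_sed"].to_numpy() / p.porosity
        cell_internal = t["icno3_sed"].to_numpy() / (
            p.cell_density(mid) * p.biovolume * 1e-12
        )
        np.testing.assert_allclose(cell_internal / pw_conc, p.enrichment, rtol=1e-12)
        # 2-3 orders of magnitude under admissible defaults
        assert 100 <= p.enrichment <= 1000

    def test_fuco_chl_profile_matches_field_ranges(self, default_params):
        """Noise-free surface and 10-cm Fuco/Chl a fall in the observed ranges."""
        p = default_params.replace(noise_cv=0.0)
        t = simulate_truth(p)
        surf = t[t["top_cm"] == 0]
        deep = t[t["top_cm"] == 9]
        surf_ratio = surf["fucoxanthin"] / surf["chlorophyll_a"]
        deep_ratio = deep["fucoxanthin"] / deep["chlorophyll_a"]
        assert surf_ratio.between(0.45, 1.20).all()
        assert deep_ratio.between(0.08, 0.29).all()

    def test_icno3_fuco_declines_with_depth_in_expectation(self, default_params):
        p = default_params.replace(noise_cv=0.0)
        t = simulate_truth(p)
        by_depth = t.groupby("top_cm").apply(
            lambda g: (g["icno3_sed"] / g["fucoxanthin"]).mean(), include_groups=False
        )
        assert (np.diff(by_depth.to_numpy()) < 0).all()

    def test_surface_layer_ratio_exceeds_deep_layer(self, default_params):
        """Mean thresholded ICNO3/Fuco at 0-1 cm exceeds that at 4-5 cm."""
        meas, pig, _ = simulate_dataset(default_params)
        pools = partition_table(meas)
        m = slice_metrics(pools, pig, DEFAULT_FUCO_THRESHOLD)
        top = m.loc[m["top_cm"] == 0, "icno3_fuco"].mean()
        mid = m.loc[m["top_cm"] == 4, "icno3_fuco"].mean()
        assert top > mid


class TestForwardMeasurement:
    def test_inverse_pair_identity_at_zero_noise(self, default_params):
        p = default_params.replace(noise_cv=0.0)
        truth = simulate_truth(p)
        pools = partition_table(forward_measurement(truth, p))
        np.testing.assert_allclose(
            pools["pwno3_sed"], truth["pwno3_sed"], rtol=1e-9
        )
        np.testing.assert_allclose(
            pools["icno3_raw"], truth["icno3_sed"], rtol=1e-9, atol=1e-12
        )

    def test_worked_inverse_example(self, default_params):
        """pwno3 = 6.876 µmol dm⁻³ with V_pw=4, added=3, V_sed=10.18 maps
        back to a 10 µmol L⁻¹ first extract."""
        p = default_params.replace(
            noise_cv=0.0, porosity=4.0 / 10.18, sediment_volume=10.18
        )
        truth = simulate_truth(p).iloc[:1].copy()
        truth["pwno3_sed"] = 10.0 * 7.0 / 10.18
        truth["icno3_sed"] = 0.0
        meas = forward_measurement(truth, p)
        assert meas["extract1_umolL"].iloc[0] == pytest.approx(10.0, rel=1e-12)
        assert meas["extract2_umolL"].iloc[0] == pytest.approx(10.0, rel=1e-12)

    def test_measurement_noise_is_seed_stable(self, default_params):
        a, _, _ = simulate_dataset(default_params)
        b, _, _ = simulate_dataset(default_params)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self, default_params):
        a, _, _ = simulate_dataset(default_params)
        b, _, _ = simulate_dataset(default_params.replace(seed=2))
        assert not a["extract1_umolL"].equals(b["extract1_umolL"])


class TestPipelineStructure:
    def test_total_pool_exceeds_porewater_pool(self, default_params):
        """Including the intracellular pool raises the areal nitrate
        inventory by at least half over porewater alone."""
        meas, pig, _ = simulate_dataset(default_params)
        pools = partition_table(meas)
        areal = areal_table(pools, pig)
        total = (areal["pwno3_areal"] + areal["icno3_areal"]).sum()
        assert total / areal["pwno3_areal"].sum() >= 1.5
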