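"""Mass-balance partitioning of the two-stage extraction protocol."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from sednitrate import ValidationError
from sednitrate.partition import (
    DepthInterval,
    SliceMeasurement,
    areal_contents,
    depth_integrate,
    partition_slice,
    partition_table,
    porewater_volume,
)


def make_slice(**kw):
    defaults = dict(
        core_id="c1",
        month=1,
        interval=DepthInterval(0, 1),
        wet_mass=15.0,
        dry_mass=11.0,
        extract1_conc=10.0,
        extract2_conc=20.0,
        added_volume=3.0,
        removed_volume=0.5,
        sediment_volume=10.18,
    )
    defaults.update(kw)
    return SliceMeasurement(**defaults)


class TestPorewaterVolume:
    @pytest.mark.parametrize(
        "wet, dry, rho, expected",
        [(15.0, 11.0, 1.0, 4.0), (11.0, 11.0, 1.0, 0.0), (15.0, 11.0, 1.016, 4.0 / 1.016)],
    )
    def test_mass_difference_over_density(self, wet, dry, rho, expected):
        assert porewater_volume(wet, dry, rho) == pytest.approx(expected)

    def test_impossible_masses_name_the_slice(self):
        with pytest.raises(ValidationError, match="core7"):
            porewater_volume(10.0, 11.0, label="core7")


class TestPartitionSlice:
    def test_hand_mass_balance(self):
        # 10 µmol/L in 7 mL liquid over 10.18 cm³ of sediment
        r = partition_slice(make_slice())
        assert r.pwno3_sed == pytest.approx(6.876, abs=5e-4)
        assert r.pw_conc == pytest.approx(17.5)
        # 10 µmol/L excess in 6.5 mL after removing 0.5 mL
        assert r.icno3_sed == pytest.approx(6.385, abs=5e-4)

    def test_equal_extracts_mean_no_cellular_release(self):
        r = partition_slice(make_slice(extract2_conc=10.0))
        assert r.icno3_sed == 0.0

    def test_naive_v2_uses_full_first_volume(self):
        r = partition_slice(make_slice(), naive_v2=True)
        assert r.icno3_sed == pytest.approx(10.0 * 7.0 / 10.18)

    def test_negative_icno3_clamped_but_kept_raw(self):
        r = partition_slice(make_slice(extract1_conc=10.0, extract2_conc=8.0))
        assert r.icno3_sed == 0.0
        assert r.icno3_raw < 0

    def test_dry_slice_has_undefined_porewater_concentration(self):
        r = partition_slice(make_slice(wet_mass=11.0))
        assert math.isnan(r.pw_conc)
        assert r.pwno3_sed > 0  # added NaCl still extracts adsorbed nitrate

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValidationError):
            make_slice(extract1_conc=-1.0)

    def test_nonpositive_second_volume_rejected(self):
        with pytest.raises(ValidationError, match="V2"):
            partition_slice(make_slice(wet_mass=11.0, added_volume=0.4))

    @given(
        e1=st.floats(0.01, 100),
        e2=st.floats(0.01, 100),
        scale=st.floats(0.1, 10),
    )
    def test_linearity_in_extract_concentrations(self, e1, e2, scale):
        base = partition_slice(make_slice(extract1_conc=e1, extract2_conc=e2))
        scaled = partition_slice(
            make_slice(extract1_conc=e1 * scale, extract2_conc=e2 * scale)
        )
        assert scaled.pwno3_sed == pytest.approx(base.pwno3_sed * scale, rel=1e-12)
        assert scaled.icno3_raw == pytest.approx(base.icno3_raw * scale, rel=1e-12)

    @given(removed=st.floats(0.0, 3.0))
    def test_pwno3_independent_of_removed_volume(self, removed):
        r = partition_slice(make_slice(removed_volume=removed))
        ref = partition_slice(make_slice(removed_volume=0.0))
        assert r.pwno3_sed == ref.pwno3_sed

    @given(e2=st.floats(0.0, 200))
    def test_icno3_monotone_in_second_extract(self, e2):
        lo = partition_slice(make_slice(extract2_conc=e2))
        hi = partition_slice(make_slice(extract2_conc=e2 + 1.0))
        assert hi.icno3_sed >= lo.icno3_sed


class TestDepthIntegrate:
    def test_unit_conversion(self):
        prof = [(DepthInterval(0, 1), 10.0), (DepthInterval(1, 2), 5.0)]
        assert depth_integrate(prof, 2.0) == pytest.approx(150.0)

    def test_constant_over_ten_cm_is_exact(self):
        prof = [(DepthInterval(i, i + 1), 1.0) for i in range(10)]
        assert depth_integrate(prof, 10.0) == 100.0

    def test_all_zero_profile(self):
        prof = [(DepthInterval(i, i + 1), 0.0) for i in range(10)]
        assert depth_integrate(prof, 10.0) == 0.0

    def test_gap_rejected_unless_allowed(self):
        prof = [(DepthInterval(0, 1), 1.0), (DepthInterval(2, 3), 1.0)]
        with pytest.raises(ValidationError, match="gap"):
            depth_integrate(prof, 3.0)
        assert depth_integrate(prof, 3.0, allow_gaps=True) == pytest.approx(20.0)

    def test_overlap_rejected(self):
        prof = [(DepthInterval(0, 2), 1.0), (DepthInterval(1, 3), 1.0)]
        with pytest.raises(ValidationError, match="overlap"):
            depth_integrate(prof, 3.0)


class TestTableLevel:
    def make_table(self, n_slices=3):
        return pd.DataFrame(
            {
                "core_id": ["c1"] * n_slices,
                "month": [1] * n_slices,
                "top_cm": np.arange(n_slices, dtype=float),
                "bottom_cm": np.arange(n_slices, dtype=float) + 1,
                "wet_g": 15.0,
                "dry_g": 11.0,
                "extract1_umolL": 10.0,
                "extract2_umolL": 20.0,
            }
        )

    def test_row_conservation_and_defaults(self):
        out = partition_table(self.make_table())
        assert len(out) == 3
        # optional protocol columns take the documented defaults
        assert out["pwno3_sed"].iloc[0] == pytest.approx(10.0 * 7.0 / 10.178760, rel=1e-5)

    def test_missing_column_named(self):
        bad = self.make_table().drop(columns="wet_g")
        with pytest.raises(ValidationError, match="wet_g"):
            partition_table(bad)

    def test_malformed_cell_reports_row(self):
        bad = self.make_table()
        bad["extract1_umolL"] = bad["extract1_umolL"].astype(object)
        bad.loc[1, "extract1_umolL"] = "oops"
        with pytest.raises(ValidationError, match="row 1"):
            partition_table(bad)

    def test_areal_contents_per_core(self):
        pools = partition_table(self.make_table())
        areal = areal_contents(pools, variables=("pwno3_sed",), max_depth=3.0)
        assert len(areal) == 1
        expected = pools["pwno3_sed"].iloc[0] * 3 * 10
        assert areal["areal_umol_m2"].iloc[0] == pytest.approx(expected)


def test_depth_interval_invariants():
    with pytest.raises(ValidationError):
        DepthInterval(2, 1)
    with pytest.raises(ValidationError):
        DepthInterval(-1, 1)
    assert DepthInterval(0.0, 1.0).thickness == 1.0
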