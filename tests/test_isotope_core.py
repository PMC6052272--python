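"""MIMS calibration, drift correction and excess-¹⁵N computation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from n15mats.isotope_core import (
    GASES,
    AirIsotopeRatios,
    CalibrationSet,
    ExcessIsotopes,
    GasConcentrations,
    MIMSReading,
    calibrate,
    check_conversion_efficiency,
    drift_correct,
    excess_n2,
    read_mims_csv,
    total_excess15N,
)

REF = {"Ar": 12.0, "O2": 300.0, "N28": 420.0, "N29": 3.1, "N30": 0.006}


def reading(sample_id="s", run_index=0, time_h=0.0, **signals) -> MIMSReading:
    base = {g: 1.0 for g in GASES}
    base.update(signals)
    return MIMSReading(sample_id, run_index, time_h, base)


@pytest.fixture
def cal() -> CalibrationSet:
    blank = reading("blank", **{g: 10.0 for g in GASES})
    std = reading("std", **{g: 110.0 for g in GASES})
    return CalibrationSet(blank=blank, air_saturated=std,
                          reference_concentrations=REF)


class TestCalibrate:
    def test_blank_signal_maps_to_zero(self, cal):
        conc = calibrate(reading(**{g: 10.0 for g in GASES}), cal)
        assert all(conc[g] == 0.0 for g in GASES)

    def test_standard_signal_maps_to_reference(self, cal):
        conc = calibrate(reading(**{g: 110.0 for g in GASES}), cal)
        assert all(conc[g] == pytest.approx(REF[g]) for g in GASES)

    def test_midpoint_signal_maps_to_half_reference(self, cal):
        conc = calibrate(reading(**{g: 60.0 for g in GASES}), cal)
        assert all(conc[g] == pytest.approx(REF[g] / 2) for g in GASES)

    def test_below_blank_clipped_and_flagged(self, cal):
        conc = calibrate(reading(Ar=5.0, **{g: 60.0 for g in GASES if g != "Ar"}), cal)
        assert conc["Ar"] == 0.0
        assert conc.clipped_gases == ("Ar",)

    def test_degenerate_standard_rejected(self):
        blank = reading("blank", **{g: 10.0 for g in GASES})
        with pytest.raises(ValueError, match="not above blank"):
            CalibrationSet(blank=blank, air_saturated=blank,
                           reference_concentrations=REF)

    @given(conc=st.fixed_dictionaries(
        {g: st.floats(0.0, 500.0, allow_nan=False) for g in GASES}))
    @settings(max_examples=50, deadline=None)
    def test_inverse_signal_model_identity(self, conc):
        """Signals synthesised from the linear model calibrate back to the
        generating concentrations exactly (zero-noise identity)."""
        blank = reading("blank", **{g: 10.0 for g in GASES})
        std = reading("std", **{g: 110.0 for g in GASES})
        cal = CalibrationSet(blank=blank, air_saturated=std,
                             reference_concentrations=REF)
        synthetic = reading(**{
            g: 10.0 + conc[g] / REF[g] * 100.0 for g in GASES
        })
        out = calibrate(synthetic, cal)
        for g in GASES:
            assert out[g] == pytest.approx(conc[g], rel=1e-12, abs=1e-9)


class TestDriftCorrect:
    def test_single_standard_flat_drift_is_identity(self):
        samples = [reading("a", 1, Ar=50.0), reading("b", 3, Ar=70.0)]
        out = drift_correct(samples, [reading("std", 0, **{g: 100.0 for g in GASES})])
        assert [r.signals["Ar"] for r in out] == [50.0, 70.0]

    def test_identical_bracketing_standards_are_identity(self):
        stds = [reading("s1", 0, **{g: 100.0 for g in GASES}),
                reading("s2", 10, **{g: 100.0 for g in GASES})]
        out = drift_correct([reading("a", 5, N28=42.0)], stds)
        assert out[0].signals["N28"] == pytest.approx(42.0)

    def test_linear_drift_interpolated_at_midpoint(self):
        # standards drift 100 -> 120; a sample reading 110 at the midpoint
        # index sits exactly on the drift line and corrects to 100
        stds = [reading("s1", 0, **{g: 100.0 for g in GASES}),
                reading("s2", 10, **{g: 120.0 for g in GASES})]
        out = drift_correct([reading("a", 5, **{g: 110.0 for g in GASES})], stds)
        assert out[0].signals["Ar"] == pytest.approx(100.0)

    def test_zero_standard_signal_rejected(self):
        with pytest.raises(ValueError, match="standard signal"):
            drift_correct([reading("a", 1)], [reading("std", 0, Ar=0.0)])


class TestExcess:
    def test_air_composition_gives_zero_excess(self):
        ratios = AirIsotopeRatios()
        c28 = 400.0
        conc = GasConcentrations({"Ar": 10, "O2": 250, "N28": c28,
                                  "N29": ratios.r29 * c28, "N30": ratios.r30 * c28})
        exc = excess_n2(conc, ratios)
        assert exc.excess29 == pytest.approx(0.0, abs=1e-12)
        assert exc.excess30 == pytest.approx(0.0, abs=1e-12)
        assert exc.total_excess15N == pytest.approx(0.0, abs=1e-12)

    def test_pure_30n2_spike_counts_twice(self):
        ratios = AirIsotopeRatios()
        c28, delta = 400.0, 0.25
        conc = GasConcentrations({"Ar": 10, "O2": 250, "N28": c28,
                                  "N29": ratios.r29 * c28,
                                  "N30": ratios.r30 * c28 + delta})
        exc = excess_n2(conc, ratios)
        assert exc.excess29 == pytest.approx(0.0, abs=1e-12)
        assert exc.excess30 == pytest.approx(delta)
        assert exc.total_excess15N == pytest.approx(2 * delta)

    @pytest.mark.parametrize("f", [0.1, 0.3, 0.5, 0.99])
    def test_random_pairing_spike_total_is_2f_times_added(self, f):
        """Binomial bookkeeping oracle: N₂ formed by random pairing at label
        fraction F contributes fractions 2F(1−F) and F² to masses 29/30, so
        the total excess ¹⁵N is exactly 2F × (added N₂)."""
        ratios = AirIsotopeRatios()
        c28, added = 400.0, 0.8
        conc = GasConcentrations({
            "Ar": 10, "O2": 250,
            "N28": c28 + (1 - f) ** 2 * added,
            "N29": ratios.r29 * c28 + 2 * f * (1 - f) * added,
            "N30": ratios.r30 * c28 + f**2 * added,
        })
        exc = excess_n2(conc, ratios)
        # the 28-mass contribution of the pairing perturbs the air baseline
        baseline_shift = (1 - f) ** 2 * added * (ratios.r29 + 2 * ratios.r30)
        assert exc.total_excess15N == pytest.approx(
            2 * f * added - baseline_shift, rel=1e-12
        )
        # the baseline shift is tiny at natural air ratios (< 0.006 μM here)
        assert exc.total_excess15N == pytest.approx(2 * f * added, abs=6e-3)

    def test_missing_isotopologue_rejected(self):
        with pytest.raises(ValueError, match="N30"):
            excess_n2(GasConcentrations({"N28": 1.0, "N29": 0.01}), AirIsotopeRatios())

    @given(
        e1=st.tuples(st.floats(-1, 1), st.floats(-1, 1)),
        e2=st.tuples(st.floats(-1, 1), st.floats(-1, 1)),
    )
    @settings(max_examples=100, deadline=None)
    def test_total_excess_is_linear(self, e1, e2):
        a = ExcessIsotopes(*e1)
        b = ExcessIsotopes(*e2)
        summed = ExcessIsotopes(a.excess29 + b.excess29, a.excess30 + b.excess30)
        assert total_excess15N(summed) == pytest.approx(
            total_excess15N(a) + total_excess15N(b), rel=1e-9, abs=1e-12
        )

    @pytest.mark.parametrize(
        "e29, e30, total", [(0.0, 0.0, 0.0), (1.0, 0.5, 2.0), (-0.1, 0.3, 0.5)]
    )
    def test_total_excess_values(self, e29, e30, total):
        assert total_excess15N(ExcessIsotopes(e29, e30)) == pytest.approx(total)


class TestAirRatios:
    @given(x=st.floats(1e-6, 0.5))
    @settings(max_examples=50, deadline=None)
    def test_binomial_ratio_identities(self, x):
        r = AirIsotopeRatios(x)
        assert r.r29 == pytest.approx(2 * x / (1 - x), rel=1e-12)
        assert r.r30 == pytest.approx((x / (1 - x)) ** 2, rel=1e-12)

    def test_natural_abundance_defaults(self):
        r = AirIsotopeRatios()
        assert r.r29 == pytest.approx(7.347e-3, rel=1e-3)
        assert r.r30 == pytest.approx(1.35e-5, rel=2e-3)


class TestConversionQC:
    @pytest.mark.parametrize("fraction, ok", [(0.96, True), (0.95, False), (1.0, True)])
    def test_threshold_is_strict(self, fraction, ok):
        assert check_conversion_efficiency(fraction) is ok

    @pytest.mark.parametrize("bad", [-0.01, 1.01, float("nan")])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            check_conversion_efficiency(bad)


def test_mims_csv_roundtrip(tmp_path):
    path = tmp_path / "mims.csv"
    path.write_text(
        "sample_id,run_index,time_h,sig_Ar,sig_O2,sig_28N2,sig_29N2,sig_30N2\n"
        "b,2,1.5,1,2,3,4,5\n"
        "a,1,0.5,6,7,8,9,10\n"
    )
    readings = read_mims_csv(path)
    assert [r.sample_id for r in readings] == ["a", "b"]  # ordered by run index
    assert readings[1].signals == {"Ar": 1, "O2": 2, "N28": 3, "N29": 4, "N30": 5}


def test_mims_csv_missing_column(tmp_path):
    path = tmp_path / "mims.csv"
    path.write_text("sample_id,run_index,time_h,sig_Ar\nx,0,0,1\n")
    with pytest.raises(ValueError, match="missing columns"):
        read_mims_csv(path)
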