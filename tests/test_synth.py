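import numpy as np
import pytest
from scipy import stats as sps

import excitoq as xq
from excitoq.synth import EndpointParams
from excitoq.viability import MTTKinetics
from excitoq import mtt_initial_rate


class TestCalciumCohort:
    def test_same_seed_identical_cohorts(self):
        p = xq.preset("cortical", n_cells=10, seed=5)
        a = xq.gen_calcium_cohort(p)
        b = xq.gen_calcium_cohort(p)
        for ta, tb in zip(a.traces, b.traces):
            np.testing.assert_array_equal(ta.values, tb.values)
        assert a.truth.equals(b.truth)

    def test_dcd_fraction_within_binomial_interval(self):
        p = xq.SynthCohortParams(n_cells=500, p_dcd=0.8, seed=11)
        cohort = xq.gen_calcium_cohort(p)
        frac = cohort.truth["has_dcd"].mean()
        half = 1.96 * np.sqrt(0.8 * 0.2 / 500)
        assert abs(frac - 0.8) < half

    def test_cortical_true_lag_median_near_180(self):
        cohort = xq.gen_calcium_cohort(xq.preset("cortical", seed=3))
        med = cohort.truth["lag_true_s"].dropna().median()
        assert med == pytest.approx(180.0, rel=0.10)

    def test_non_monotone_event_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            xq.SynthCohortParams(glu_on=500.0, glu_off=400.0)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="p_dcd"):
            xq.SynthCohortParams(p_dcd=1.5)

    def test_trace_phenomenology(self):
        """Baseline plateau, first-phase rise, washout decay, iono saturation."""
        p = xq.SynthCohortParams(n_cells=4, p_dcd=1.0, noise_sd=0.0, seed=1)
        cohort = xq.gen_calcium_cohort(p)
        tr = cohort.traces[0]
        pre = tr.values[tr.time < p.glu_on]
        np.testing.assert_allclose(pre, p.baseline)
        plateau = tr.values[(tr.time > p.glu_on + 60) & (tr.time < p.glu_on + 80)]
        assert np.all(plateau > p.baseline + 0.9 * p.first_phase_amplitude)
        # relaxes toward baseline during washout
        at_off = np.interp(p.glu_off, tr.time, tr.values)
        before_fccp = np.interp(p.fccp_on - 20, tr.time, tr.values)
        assert before_fccp < at_off
        # ionomycin saturates high
        assert tr.values[-1] > p.baseline + 0.9 * p.iono_amplitude


@pytest.fixture(scope="module")
def pair():
    p = xq.SynthCohortParams(n_cells=30, seed=9, noise_sd=0.0)
    ca = xq.gen_calcium_cohort(p)
    return ca, xq.gen_mito_cohort(ca)


class TestMitoCohort:
    def test_nondcd_cells_back_to_unity_before_fccp(self, pair):
        ca, mito = pair
        p = ca.params
        non = set(ca.truth.loc[~ca.truth["has_dcd"], "cell_id"])
        assert non, "fixture needs at least one non-DCD cell"
        for tr in mito.traces:
            if tr.cell_id in non:
                pre_fccp = np.interp(p.fccp_on - 20, tr.time, tr.values)
                assert pre_fccp == pytest.approx(1.0, abs=0.02)

    def test_depolarization_onset_matches_calcium_ground_truth(self, pair):
        ca, mito = pair
        p = ca.params
        merged = ca.truth.merge(mito.truth, on="cell_id", suffixes=("_ca", "_mito"))
        dcd = merged[merged["has_dcd_ca"]]
        np.testing.assert_allclose(
            dcd["depol_onset_s"],
            p.glu_on + dcd["lag_true_s"],
            atol=p.sampling_interval,
        )

    def test_lps_slows_rh123_washout_slope(self):
        slopes = {}
        for f in (1.0, 0.5):
            p = xq.SynthCohortParams(n_cells=25, seed=13, lps_recovery_factor=f)
            mito = xq.gen_mito_cohort(xq.gen_calcium_cohort(p))
            vals = [
                xq.rh123_recovery_slope(tr, (p.glu_off, p.fccp_on - 15))[0]
                for tr in mito.traces
            ]
            slopes[f] = np.mean(np.abs(vals))
        assert slopes[0.5] < slopes[1.0]

    def test_mismatched_cell_ids_rejected(self, pair):
        ca, _ = pair
        broken = xq.CalciumCohort(
            ca.traces[:-1], ca.truth, ca.events, ca.params
        )
        with pytest.raises(ValueError, match="cell ids"):
            xq.gen_mito_cohort(broken)


class TestIonTraces:
    def test_sodium_recovers_more_slowly_than_calcium(self):
        p = xq.SynthCohortParams(n_cells=1, p_dcd=0.0, seed=21, noise_sd=0.0)
        ca = xq.gen_calcium_cohort(p).traces[0]
        na = xq.gen_ion_trace("sodium", p)
        window = (p.glu_off, p.fccp_on - 20)

        def halftime(tr):
            base = tr.values[tr.time < p.glu_on].mean()
            start = float(np.interp(p.glu_off, tr.time, tr.values))
            return xq.recovery_halftime(tr, window, base, start)

        h_na = halftime(na)
        h_ca = halftime(ca)
        assert h_ca is not None and h_na is not None
        assert h_na > h_ca

    def test_no_glu_control_is_flat(self):
        p = xq.SynthCohortParams(seed=3, noise_sd=0.01)
        tr = xq.gen_ion_trace("sodium", p, glu=False)
        assert np.all(np.abs(tr.values - p.baseline) < 5 * p.noise_sd)

    def test_dibac_rises_at_glu_on(self):
        p = xq.SynthCohortParams(seed=3, noise_sd=0.0)
        tr = xq.gen_ion_trace("dibac", p)
        mid_glu = np.interp((p.glu_on + p.glu_off) / 2, tr.time, tr.values)
        assert mid_glu > p.baseline + 0.8 * p.dibac_amplitude

    def test_seeded_determinism(self):
        p = xq.SynthCohortParams(seed=17)
        a = xq.gen_ion_trace("sodium", p)
        b = xq.gen_ion_trace("sodium", p)
        np.testing.assert_array_equal(a.values, b.values)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            xq.gen_ion_trace("potassium", xq.SynthCohortParams())


class TestOcrPlate:
    def test_blank_wells_have_no_injection_response(self):
        plate, _ = xq.gen_ocr_plate(xq.SynthPlateParams(seed=2, noise_sd=0.0))
        blanks = plate.ocr[plate.blank]
        # pure shared drift: every blank row is identical and injection-free
        for row in blanks:
            np.testing.assert_allclose(row, blanks[0])

    def test_ground_truth_identity_maximal_basal_src(self):
        _, truth = xq.gen_ocr_plate(xq.SynthPlateParams(seed=8))
        np.testing.assert_array_equal(truth["maximal"], truth["basal"] + truth["src"])

    def test_noiseless_plate_recovers_ground_truth(self):
        plate, truth = xq.gen_ocr_plate(xq.SynthPlateParams(seed=4, noise_sd=0.0))
        metrics = xq.compute_flux_metrics(xq.blank_correct(plate))
        merged = metrics.table.merge(truth, on="well", suffixes=("_est", "_true"))
        for col in ("nocr", "basal", "maximal", "src"):
            np.testing.assert_allclose(
                merged[f"{col}_est"], merged[f"{col}_true"], rtol=1e-9, atol=1e-9
            )

    def test_injection_beyond_plate_rejected(self):
        with pytest.raises(ValueError, match="injection cycles"):
            xq.SynthPlateParams(injection_ports=(("glu", 4), ("fccp", 8), ("antrot", 99)))

    def test_seeded_determinism(self):
        p = xq.SynthPlateParams(seed=6)
        a, _ = xq.gen_ocr_plate(p)
        b, _ = xq.gen_ocr_plate(p)
        np.testing.assert_array_equal(a.ocr, b.ocr)


class TestEndpointTables:
    def test_survival_fraction_within_binomial_interval(self):
        p = EndpointParams(
            survival_probs={"x": 0.5}, n_cells_counted=1000, n_replicates=1, seed=5
        )
        via, _, _ = xq.gen_endpoint_tables(p)
        frac = via["n_live"].sum() / (via["n_live"].sum() + via["n_dead"].sum())
        half = 1.96 * np.sqrt(0.25 / 1000)
        assert abs(frac - 0.5) < half

    def test_area_factor_gives_expected_mean_change(self):
        p = EndpointParams(
            area_factors={"glu": 1.427}, n_experiments=20, cells_per_experiment=50, seed=3
        )
        _, _, areas = xq.gen_endpoint_tables(p)
        pct = xq.area_change_percent(
            areas["area_before_px"].to_numpy(), areas["area_after_px"].to_numpy()
        )
        assert pct.mean() == pytest.approx(42.7, abs=1.5)

    def test_mtt_slope_recovered_on_noiseless_kinetics(self):
        p = EndpointParams(mtt_noise_sd=0.0, seed=1)
        _, mtt, _ = xq.gen_endpoint_tables(p)
        for cond, rate in p.mtt_rates.items():
            sub = mtt[mtt["condition"] == cond]
            kin = MTTKinetics(
                sub["time_min"].to_numpy(), sub["a550"].to_numpy(), sub["a_bg"].to_numpy()
            )
            est = mtt_initial_rate(kin, window_min=10.0)
            assert est.rate_od_per_min == pytest.approx(rate, rel=1e-9)

    def test_negative_probability_rejected(self):
        with pytest.raises(ValueError):
            EndpointParams(survival_probs={"x": -0.1})

    def test_seeded_determinism(self):
        a = xq.gen_endpoint_tables(EndpointParams(seed=9))
        b = xq.gen_endpoint_tables(EndpointParams(seed=9))
        for ta, tb in zip(a, b):
            assert ta.equals(tb)


def test_decreasing_lps_factor_decreases_true_recovery():
    """Monotone link between the LPS factor and ground-truth recovery."""
    meds = []
    for f in (1.0, 0.7, 0.4):
        p = xq.SynthCohortParams(n_cells=5, seed=2, lps_recovery_factor=f)
        meds.append(xq.gen_calcium_cohort(p).truth["recovery_true_pct"].median())
    assert meds[0] > meds[1] > meds[2]
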