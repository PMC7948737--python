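"""SPR referencing, affinity fits, theoretical Rmax, and SEC calibration."""

import numpy as np
import pytest

from glycokinetics.biophysics import (
    double_reference,
    estimate_mw,
    extract_req,
    fit_kinetic_1to1,
    fit_sec_calibration,
    fit_steady_state,
    solvent_correct,
    theoretical_rmax,
)
from glycokinetics.data import NoiseSpec, Sensorgram
from glycokinetics.synthetic_data import (
    SEC_STANDARDS,
    SPR_SERIES_UM,
    simulate_sec_elution,
    simulate_sensorgram_family,
)


def family_pieces(fam):
    act = {g.cycle_id: g for g in fam if g.role == "active" and g.analyte_conc > 0}
    ref = {g.cycle_id: g for g in fam if g.role == "reference" and g.analyte_conc > 0}
    ba = next(g for g in fam if g.role == "active" and g.analyte_conc == 0)
    br = next(g for g in fam if g.role == "reference" and g.analyte_conc == 0)
    return act, ref, ba, br


def corrected_family(**kwargs):
    defaults = dict(kd=140.0, kon=1e4, rmax=40.0, conc_series=SPR_SERIES_UM,
                    bulk_ri=5.0, drift=0.01, noise=NoiseSpec())
    defaults.update(kwargs)
    fam = simulate_sensorgram_family(**defaults)
    act, ref, ba, br = family_pieces(fam)
    return [double_reference(act[c], ref[c], ba, br) for c in act]


class TestDoubleReferencing:
    def test_recovers_pure_langmuir_curve_exactly(self):
        """Bulk pulse and both cells' drift cancel to <= 1e-9 RU without noise."""
        corr = corrected_family()
        clean = simulate_sensorgram_family(
            kd=140.0, kon=1e4, rmax=40.0, conc_series=SPR_SERIES_UM,
            bulk_ri=0.0, drift=0.0, noise=NoiseSpec(),
        )
        clean_act = {g.cycle_id: g for g in clean if g.role == "active" and g.analyte_conc > 0}
        for c in corr:
            assert np.max(np.abs(c.response - clean_act[c.cycle_id].response)) <= 1e-9

    def test_self_subtraction_is_identically_zero(self):
        fam = simulate_sensorgram_family(
            kd=140.0, kon=1e4, rmax=40.0, conc_series=[0.0], bulk_ri=5.0, drift=0.01,
            noise=NoiseSpec(), n_blanks=1,
        )
        act, ref, ba, br = family_pieces(fam)
        corr = double_reference(ba, br, ba, br)
        assert np.allclose(corr.response, 0.0)

    def test_mismatched_time_grids_interpolated(self):
        fam = simulate_sensorgram_family(kd=140.0, kon=1e4, rmax=40.0, conc_series=[200.0],
                                         noise=NoiseSpec())
        act, ref, ba, br = family_pieces(fam)
        # resample the reference on a denser grid covering the active range
        dense_t = np.linspace(ref.times[0] if False else act[list(act)[0]].times[0],
                              ba.times[-1], 4001)
        r = list(ref.values())[0]
        dense_ref = Sensorgram(
            times=dense_t, response=np.interp(dense_t, r.times, r.response),
            analyte_conc=r.analyte_conc, role=r.role,
            injection_start=r.injection_start, injection_stop=r.injection_stop,
            cycle_id=r.cycle_id,
        )
        corr = double_reference(list(act.values())[0], dense_ref, ba, br)
        assert corr.times.size == list(act.values())[0].times.size

    def test_disjoint_time_ranges_rejected(self):
        fam = simulate_sensorgram_family(kd=140.0, kon=1e4, rmax=40.0, conc_series=[200.0],
                                         noise=NoiseSpec())
        act, ref, ba, br = family_pieces(fam)
        a = list(act.values())[0]
        shifted = Sensorgram(
            times=a.times + 1e4, response=a.response, analyte_conc=a.analyte_conc,
            role="reference", injection_start=a.injection_start + 1e4,
            injection_stop=a.injection_stop + 1e4, cycle_id=a.cycle_id,
        )
        with pytest.raises(ValueError, match="overlap"):
            double_reference(a, shifted, ba, br)


class TestSolventCorrection:
    def test_zero_map_is_identity(self):
        corr = corrected_family()[0]
        out = solvent_correct(corr, (np.array([0.0, 10.0]), np.array([0.0, 0.0])))
        assert np.array_equal(out.response, corr.response)

    def test_constant_offset_shifts_by_minus_c(self):
        corr = corrected_family()[0]
        out = solvent_correct(corr, (np.array([0.0, 10.0]), np.array([0.7, 0.7])))
        assert np.allclose(corr.response - out.response, 0.7)

    def test_known_dmso_mismatch_removed(self):
        """Generator's active-cell-only mismatch is removed via the calibration map."""
        mismatch = 1.5
        fam = simulate_sensorgram_family(
            kd=140.0, kon=1e4, rmax=40.0, conc_series=[200.0], bulk_ri=5.0,
            drift=0.0, solvent_mismatch=mismatch, noise=NoiseSpec(),
        )
        act, ref, ba, br = family_pieces(fam)
        corr = double_reference(list(act.values())[0], list(ref.values())[0], ba, br)
        # residual mismatch survives double referencing during the injection
        inj = corr.association_mask()
        assert corr.response[inj][0] == pytest.approx(mismatch, abs=1e-9)
        # the calibration maps reference excess (5 RU) to the known correction
        cal = (np.array([0.0, 5.0, 10.0]), np.array([0.0, mismatch, 2 * mismatch]))
        fixed = solvent_correct(corr, cal)
        assert abs(fixed.response[inj][0]) <= 1e-9

    def test_out_of_domain_excess_warns(self):
        corr = corrected_family()[0]  # ref_excess = 5 RU
        with pytest.warns(UserWarning, match="solvent-calibration domain"):
            solvent_correct(corr, (np.array([0.0, 1.0]), np.array([0.0, 0.1])))


class TestReqExtraction:
    def test_flat_plateau_returns_plateau_value(self):
        t = np.arange(0.0, 200.0, 0.1)
        resp = np.where((t >= 10) & (t < 70), 17.5, 0.0)
        resp[t >= 70] = 0.0
        g = Sensorgram(times=t, response=resp, analyte_conc=100.0, role="active",
                       injection_start=10.0, injection_stop=70.0)
        pt = extract_req(g)
        assert pt.req == pytest.approx(17.5)
        assert not pt.nonequilibrium

    def test_long_association_approaches_analytic_req(self):
        corr = corrected_family(conc_series=[200.0], t_assoc=600.0, drift=0.0, bulk_ri=0.0)[0]
        pt = extract_req(corr)
        assert pt.req == pytest.approx(40.0 * 200.0 / 340.0, rel=1e-6)

    def test_one_minute_association_fast_kinetics_within_one_percent(self):
        """koff = kon*kd ~ 1.4/s settles well inside the printed 60 s association."""
        corr = corrected_family(conc_series=[200.0], t_assoc=60.0, drift=0.0, bulk_ri=0.0)[0]
        pt = extract_req(corr)
        assert pt.req == pytest.approx(40.0 * 200.0 / 340.0, rel=0.01)
        assert not pt.nonequilibrium

    def test_still_rising_flagged_nonequilibrium(self):
        # slow kinetics: kobs*t_assoc << 1
        corr = corrected_family(conc_series=[200.0], kon=10.0, t_assoc=60.0,
                                drift=0.0, bulk_ri=0.0)[0]
        assert extract_req(corr).nonequilibrium


class TestSteadyStateFit:
    def roundtrip(self, kd, rmax=40.0):
        reqs = [(c, rmax * c / (kd + c)) for c in SPR_SERIES_UM]
        return fit_steady_state(reqs)

    @pytest.mark.parametrize("kd", [140.0, 260.0])
    def test_exact_roundtrip_on_printed_series(self, kd):
        fit = self.roundtrip(kd)
        assert fit.kd == pytest.approx(kd, rel=1e-6)
        assert fit.rmax == pytest.approx(40.0, rel=1e-6)

    def test_weak_binder_raises_nonsaturation_warning(self):
        fit = self.roundtrip(5000.0)  # KD >> 200 uM top: the acceptor-like scenario
        assert fit.saturation_at_top < 0.5
        assert any("nonsaturation" in w for w in fit.warnings)

    def test_constant_response_flagged_boundary(self):
        fit = fit_steady_state([(c, 12.0) for c in SPR_SERIES_UM], fit_offset=False)
        assert any("kd_at_lower_boundary" in w for w in fit.warnings)

    def test_order_invariance_and_common_offset(self):
        pts = [(c, 40.0 * c / (140.0 + c) + 3.0) for c in SPR_SERIES_UM]
        f1 = fit_steady_state(pts)
        f2 = fit_steady_state(list(reversed(pts)))
        assert f1.kd == pytest.approx(f2.kd, rel=1e-9)
        assert f1.kd == pytest.approx(140.0, rel=1e-6)
        assert f1.offset == pytest.approx(3.0, abs=1e-6)

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_steady_state([(200.0, 20.0), (66.7, 10.0)])


class TestKinetic1to1:
    def test_noiseless_family_recovers_rates(self):
        corr = corrected_family(drift=0.0, bulk_ri=0.0)
        fit = fit_kinetic_1to1(corr)
        assert fit.converged
        assert fit.kon == pytest.approx(1e4, rel=1e-4)
        assert fit.koff == pytest.approx(1e4 * 140.0 * 1e-6, rel=1e-4)

    def test_kinetic_kd_matches_steady_state_kd(self):
        corr = corrected_family(drift=0.0, bulk_ri=0.0)
        kin = fit_kinetic_1to1(corr)
        ss = fit_steady_state([(p.conc, p.req) for p in (extract_req(c) for c in corr)])
        assert kin.kd_kinetic == pytest.approx(ss.kd, rel=0.01)

    def test_dissociation_only_recovers_koff_flags_kon(self):
        corr = corrected_family(drift=0.0, bulk_ri=0.0)
        trimmed = []
        for g in corr:
            keep = g.times >= g.injection_stop + 0.5
            trimmed.append(
                Sensorgram(
                    times=g.times[keep], response=g.response[keep],
                    analyte_conc=g.analyte_conc, role=g.role,
                    injection_start=g.times[keep][0] - 1.0,
                    injection_stop=g.times[keep][0] - 0.5,
                    cycle_id=g.cycle_id,
                )
            )
        fit = fit_kinetic_1to1(trimmed)
        assert "kon_unidentifiable" in fit.flags
        assert fit.koff == pytest.approx(1.4e-3 * 1e3, rel=1e-3)  # 1.4 per s


class TestTheoreticalRmax:
    def test_printed_surface_density_gives_value_in_printed_band(self):
        """4500 RU of a ~42 kDa ligand binding a 404 Da analyte: ~43 RU, in 30-50."""
        rmax = theoretical_rmax(4500.0, 42000.0, 404.0, valency=1)
        assert rmax == pytest.approx(4500.0 * 404.0 / 42000.0, rel=1e-12)
        assert 30.0 <= rmax <= 50.0

    def test_equal_masses_and_valency_scaling(self):
        assert theoretical_rmax(1000.0, 5e4, 5e4) == 1000.0
        assert theoretical_rmax(1000.0, 5e4, 5e4, valency=2) == 2000.0

    def test_zero_ligand_mass_rejected(self):
        with pytest.raises(ValueError):
            theoretical_rmax(1000.0, 0.0, 404.0)


class TestSEC:
    TRUTH = (4.0, -0.25)

    def standards(self, noise=NoiseSpec()):
        return [
            (mw, simulate_sec_elution(self.TRUTH, mw, noise=NoiseSpec(
                cv=noise.cv, additive_sd=noise.additive_sd, seed=noise.seed + i)))
            for i, (_, mw) in enumerate(SEC_STANDARDS)
        ]

    def test_exact_calibration_recovered(self):
        cal = fit_sec_calibration(self.standards())
        assert cal.intercept == pytest.approx(4.0, rel=1e-9)
        assert cal.slope == pytest.approx(-0.25, rel=1e-9)
        assert cal.r_squared == pytest.approx(1.0)

    def test_two_standards_rejected(self):
        with pytest.raises(ValueError, match="3 standards"):
            fit_sec_calibration(self.standards()[:2])

    def test_wrong_orientation_rejected(self):
        flipped = [(mw, -v) for mw, v in self.standards()]
        with pytest.raises(ValueError, match="elute earlier"):
            fit_sec_calibration(flipped)

    def test_roundtrip_identity_at_zero_noise(self):
        cal = fit_sec_calibration(self.standards())
        for mw in (84.0, 42.0, 300.0):
            vol = simulate_sec_elution(self.TRUTH, mw, noise=NoiseSpec())
            est = estimate_mw(vol, cal)
            assert est.mw_kda == pytest.approx(mw, rel=1e-9)
            assert not est.extrapolated

    def test_dimer_fixture_reads_twice_the_monomer(self):
        """An 84 kDa species elutes where a dimer of a 42 kDa monomer should."""
        cal = fit_sec_calibration(self.standards())
        vol = simulate_sec_elution(self.TRUTH, 2 * 42.0, noise=NoiseSpec())
        est = estimate_mw(vol, cal)
        assert est.mw_kda / 42.0 == pytest.approx(2.0, rel=0.01)

    def test_extrapolation_flagged(self):
        cal = fit_sec_calibration(self.standards())
        vols = [v for _, v in cal.standards]
        est = estimate_mw(max(vols) + 5.0, cal)
        assert est.extrapolated

    def test_noisy_calibration_slope_within_three_se(self):
        noisy = self.standards(noise=NoiseSpec(additive_sd=0.05, seed=3))
        cal = fit_sec_calibration(noisy)
        # crude SE via linregress on the same points
        from scipy import stats as ss

        mw = np.array([m for m, _ in noisy])
        vol = np.array([v for _, v in noisy])
        res = ss.linregress(vol, np.log10(mw))
        assert abs(cal.slope - (-0.25)) < 3 * res.stderr
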