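"""Peak picking, multi-Gaussian fitting, charge assignment, quantification."""

import numpy as np
import pytest

import nativeimms as ni
from conftest import deconvolute_pipeline


def make_spectrum(centres, sigmas, areas, mz_range, step=0.05, baseline=0.0):
    mz = np.arange(*mz_range, step)
    y = np.full_like(mz, baseline)
    for c, s, a in zip(centres, sigmas, areas):
        y += a / (s * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((mz - c) / s) ** 2)
    return ni.MassSpectrum(mz, y)


class TestPickPeaks:
    def test_flat_spectrum_has_no_peaks(self):
        spec = ni.MassSpectrum(np.linspace(1000, 2000, 500),
                               np.ones(500))
        assert ni.pick_peaks(spec, 0.5, 5.0) == []

    def test_recovers_generator_positions(self, wt_like_spectrum):
        truth = wt_like_spectrum.metadata["ground_truth"]
        centres = ni.pick_peaks(wt_like_spectrum, 0.02, 10.0)
        expected = sorted(p["centre"] for p in truth["peaks"])
        assert len(centres) == 7
        step = np.median(np.diff(wt_like_spectrum.mz))
        for found, want in zip(centres, expected):
            assert abs(found - want) <= step / 2 + 1e-9

    def test_close_pair_keeps_the_taller(self):
        spec = make_spectrum([1000.0, 1003.0], [1.0, 1.0], [1.0, 2.0],
                             (980, 1020))
        centres = ni.pick_peaks(spec, 0.05, min_separation=8.0)
        # brute-force oracle: global maximum of the summed profile
        tallest = spec.mz[np.argmax(spec.intensity)]
        assert len(centres) == 1
        assert centres[0] == pytest.approx(tallest, abs=0.05)

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError):
            ni.pick_peaks(ni.MassSpectrum([], []), 0.1, 1.0)


class TestMultiGaussianFit:
    def test_single_gaussian_recovered_exactly(self):
        spec = make_spectrum([1500.0], [2.5], [7.0], (1450, 1550))
        fit = ni.fit_multi_gaussian(spec, [1500.5])
        assert fit.converged
        peak = fit.peaks[0]
        assert peak.centre == pytest.approx(1500.0, rel=1e-6)
        assert peak.sigma == pytest.approx(2.5, rel=1e-6)
        assert peak.area == pytest.approx(7.0, rel=1e-6)

    def test_constant_baseline_recovered(self):
        spec = make_spectrum([1500.0], [2.5], [7.0], (1450, 1550),
                             baseline=0.4)
        fit = ni.fit_multi_gaussian(spec, [1500.0])
        assert fit.baseline == pytest.approx(0.4, rel=1e-6)
        assert fit.peaks[0].area == pytest.approx(7.0, rel=1e-6)

    def test_overlapping_pair_areas_against_component_integrals(self):
        # two overlapping Gaussians; the oracle integrates each
        # generated component separately on a fine grid
        centres, sigmas, areas = [1000.0, 1004.0], [1.8, 1.8], [3.0, 5.0]
        spec = make_spectrum(centres, sigmas, areas, (980, 1025), step=0.02)
        fit = ni.fit_multi_gaussian(spec, [999.5, 1004.5])
        mz = np.arange(980, 1025, 0.02)
        for peak, c, s, a in zip(fit.peaks, centres, sigmas, areas):
            component = a / (s * np.sqrt(2 * np.pi)) * np.exp(
                -0.5 * ((mz - c) / s) ** 2)
            oracle = np.trapezoid(component, mz)
            assert peak.area == pytest.approx(oracle, rel=0.01)

    def test_baseline_resolved_areas_within_half_percent(self,
                                                         wt_like_spectrum):
        truth = wt_like_spectrum.metadata["ground_truth"]
        centres = ni.pick_peaks(wt_like_spectrum, 0.02, 10.0)
        fit = ni.fit_multi_gaussian(wt_like_spectrum, centres)
        want = sorted(truth["peaks"], key=lambda p: p["centre"])
        for peak, ref in zip(fit.peaks, want):
            assert peak.area == pytest.approx(ref["area"], rel=5e-3)

    def test_centres_outside_range_rejected(self, wt_like_spectrum):
        with pytest.raises(ValueError):
            ni.fit_multi_gaussian(wt_like_spectrum, [99999.0])


class TestChargeAssignment:
    def test_exact_position_assigned(self):
        peak = ni.PeakFit(centre=ni.mz_for(74000.0, 17), sigma=1.0, area=1.0)
        out = ni.assign_charge_states([peak], [("dimer", 74000.0)])
        assert out[0].assigned_species == "dimer"
        assert out[0].assigned_charge == 17

    def test_envelope_assignment_matches_generator(self, wt_like_spectrum):
        truth = wt_like_spectrum.metadata["ground_truth"]
        centres = ni.pick_peaks(wt_like_spectrum, 0.02, 10.0)
        fit = ni.fit_multi_gaussian(wt_like_spectrum, centres)
        assigned = ni.assign_charge_states(
            fit.peaks, [("monomer", 37000.0), ("dimer", 74000.0)],
            allowed_charges={"monomer": range(11, 14),
                             "dimer": range(16, 20)})
        want = {(round(p["centre"], 1)): (p["species"], p["charge"])
                for p in truth["peaks"]}
        for peak in assigned:
            species, charge = want[round(peak.centre, 1)]
            assert peak.assigned_species == species
            assert peak.assigned_charge == charge

    def test_far_peak_stays_unassigned(self):
        peak = ni.PeakFit(centre=1234.5, sigma=1.0, area=1.0)
        out = ni.assign_charge_states([peak], [("dimer", 74000.0)],
                                      tolerance=0.05)
        assert out[0].assigned_species is None

    def test_ambiguous_tie_break_is_deterministic(self):
        # a peak equidistant-in-tolerance from two hypotheses: the
        # smaller |delta m/z| wins; verified against a brute-force scan
        mass_a, mass_b = 50000.0, 50005.0
        peak_mz = ni.mz_for(mass_a, 20) + 0.1
        peak = ni.PeakFit(centre=peak_mz, sigma=1.0, area=1.0)
        residuals = {}
        for label, mass in (("a", mass_a), ("b", mass_b)):
            for z in range(1, 100):
                residuals[(label, z)] = abs(peak_mz - ni.mz_for(mass, z))
        best = min(residuals, key=lambda k: (residuals[k], k[1], k[0]))
        out = ni.assign_charge_states([peak], [("a", mass_a), ("b", mass_b)],
                                      tolerance=2.0)
        assert (out[0].assigned_species, out[0].assigned_charge) == best


class TestNeutralMass:
    def test_exact_mass_from_three_charges(self):
        mass = 36998.4
        peaks = [ni.PeakFit(centre=ni.mz_for(mass, z), sigma=1.0, area=1.0,
                            assigned_species="m", assigned_charge=z)
                 for z in (11, 12, 13)]
        got, sd = ni.deconvolute_neutral_mass(peaks)
        assert got == pytest.approx(mass, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_single_charge_state_flags_undefined_spread(self):
        peak = ni.PeakFit(centre=ni.mz_for(37000.0, 12), sigma=1.0, area=1.0,
                          assigned_species="m", assigned_charge=12)
        got, sd = ni.deconvolute_neutral_mass([peak])
        assert got == pytest.approx(37000.0)
        assert np.isnan(sd)

    def test_two_peak_closed_form_oracle(self):
        # adjacent 30+/31+ peaks determine the mass in closed form:
        # z_high = (mz_low - mp) / (mz_high_mz - mz_low) ... compared
        # against the multi-state estimate
        mass = 37123.7
        mz31, mz30 = ni.mz_for(mass, 31), ni.mz_for(mass, 30)
        z = (mz31 - ni.PROTON_MASS) / (mz30 - mz31)
        oracle = z * (mz30 - ni.PROTON_MASS)
        peaks = [ni.PeakFit(centre=m, sigma=0.5, area=1.0,
                            assigned_species="m", assigned_charge=q)
                 for m, q in ((mz31, 31), (mz30, 30))]
        got, _ = ni.deconvolute_neutral_mass(peaks)
        assert got == pytest.approx(oracle, abs=1e-6)
        assert got == pytest.approx(mass, abs=1e-6)

    def test_phospho_ladder_classification(self):
        masses = [37000.0, 37079.966, 37159.932]
        assert ni.classify_proteoforms(masses) == [0, 1, 2]


class TestQuantifySpecies:
    def test_single_species_fraction_is_one(self):
        peaks = [ni.PeakFit(centre=4000.0, sigma=1.0, area=2.0,
                            assigned_species="dimer", assigned_charge=18)]
        table = ni.quantify_species(peaks)
        assert table.fraction("dimer") == 1.0

    def test_s337d_like_abundances(self):
        species = [
            ni.SpeciesSpec("monomer", 37000.0, [11, 12, 13], 25.2),
            ni.SpeciesSpec("dimer", 74000.0, [16, 17, 18, 19], 74.8),
        ]
        spec = ni.generate_mass_spectrum(species, (2600, 5000), 3.0)
        table = deconvolute_pipeline(
            spec, [("monomer", 37000.0), ("dimer", 74000.0)],
            {"monomer": range(11, 14), "dimer": range(16, 20)},
            labels=("monomer", "dimer"))
        assert table.fraction("monomer") == pytest.approx(0.252, abs=0.002)

    def test_monomer_fold_change_between_scenarios(self, wt_like_spectrum):
        ref = deconvolute_pipeline(
            wt_like_spectrum, [("monomer", 37000.0), ("dimer", 74000.0)],
            {"monomer": range(11, 14), "dimer": range(16, 20)},
            labels=("monomer", "dimer"))
        species = [
            ni.SpeciesSpec("monomer", 37000.0, [11, 12, 13], 25.2),
            ni.SpeciesSpec("dimer", 74000.0, [16, 17, 18, 19], 74.8),
        ]
        var = deconvolute_pipeline(
            ni.generate_mass_spectrum(species, (2600, 5000), 3.0),
            [("monomer", 37000.0), ("dimer", 74000.0)],
            {"monomer": range(11, 14), "dimer": range(16, 20)},
            labels=("monomer", "dimer"))
        fold = var.fraction("monomer") / ref.fraction("monomer")
        assert fold == pytest.approx(2.4, abs=0.1)

    def test_fraction_invariant_under_intensity_rescale(self,
                                                        wt_like_spectrum):
        scaled = ni.MassSpectrum(wt_like_spectrum.mz,
                                 wt_like_spectrum.intensity * 137.0)
        args = ([("monomer", 37000.0), ("dimer", 74000.0)],
                {"monomer": range(11, 14), "dimer": range(16, 20)})
        a = deconvolute_pipeline(wt_like_spectrum, *args)
        b = deconvolute_pipeline(scaled, *args)
        assert a.fraction("monomer") == pytest.approx(
            b.fraction("monomer"), rel=1e-6)

    def test_all_unassigned_rejected(self):
        peaks = [ni.PeakFit(centre=4000.0, sigma=1.0, area=2.0)]
        with pytest.raises(ValueError):
            ni.quantify_species(peaks)


def test_spectrum_csv_round_trip(tmp_path, wt_like_spectrum):
    path = tmp_path / "spec.csv"
    wt_like_spectrum.to_csv(path)
    back = ni.MassSpectrum.from_csv(path)
    np.testing.assert_allclose(back.mz, wt_like_spectrum.mz)
    np.testing.assert_allclose(back.intensity, wt_like_spectrum.intensity)
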