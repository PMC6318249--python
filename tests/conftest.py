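import numpy as np
import pytest

import nativeimms as ni


@pytest.fixture(scope="session")
def wt_like_species():
    """Two-species scenario: minor monomer (11+..13+), dominant dimer
    (16+..19+) at a 10.5 : 89.5 area split."""
    return [
        ni.SpeciesSpec("monomer", 37000.0, [11, 12, 13],
                       relative_abundance=10.5),
        ni.SpeciesSpec("dimer", 74000.0, [16, 17, 18, 19],
                       relative_abundance=89.5),
    ]


@pytest.fixture(scope="session")
def wt_like_spectrum(wt_like_species):
    return ni.generate_mass_spectrum(wt_like_species, (2600, 5000),
                                     peak_sigma=3.0)


@pytest.fixture(scope="session")
def known_calibration():
    """A power-law calibration with known coefficients for round trips."""
    return ni.Calibration(slope=0.55, intercept=2.0, edc_coefficient=1.41,
                          gas_mass=4.0026)


@pytest.fixture(scope="session")
def three_step_fingerprint():
    """Noiseless three-transition unfolding fingerprint on a 1-V grid."""
    truth = ni.CIUGroundTruth(conformer_centroids=[44.3, 50.0, 56.0, 63.0],
                              transition_midpoints=[40.0, 48.0, 58.0],
                              transition_widths=2.0)
    cv = np.arange(20.0, 81.0, 1.0)
    ccs = np.arange(35.0, 75.0, 0.1)
    return ni.generate_ciu_fingerprint(truth, cv, ccs, peak_sigma=1.5)


def deconvolute_pipeline(spectrum, candidates, allowed, labels=None,
                         min_height=0.02, min_sep=10.0):
    """Shared helper: peaks -> multi-Gaussian fit -> assignment -> table."""
    centres = ni.pick_peaks(spectrum, min_relative_height=min_height,
                            min_separation=min_sep)
    fit = ni.fit_multi_gaussian(spectrum, centres)
    assert fit.converged
    assigned = ni.assign_charge_states(fit.peaks, candidates,
                                       allowed_charges=allowed)
    return ni.quantify_species(assigned, labels=labels)
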