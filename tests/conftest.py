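import numpy as np
import pytest

from cortbs import synthetic_data as sd
from cortbs import spectral_estimation as se
from cortbs.frames import AcquisitionConfig


@pytest.fixture(scope="session")
def small_acq():
    """Compact acquisition used by fast unit tests."""
    return AcquisitionConfig(beam_count=16, sweep_count=4, noise_level_db=-200,
                             analysis_depth_mm=6.0, fractional_bandwidth=1.2)


@pytest.fixture(scope="session")
def recovery_acq():
    """Heavier-averaging acquisition used by recovery-accuracy tests."""
    return AcquisitionConfig(beam_count=48, sweep_count=12, noise_level_db=-200,
                             analysis_depth_mm=7.0, fractional_bandwidth=1.2)


@pytest.fixture(scope="session")
def control_profile():
    """Profile tuned to a healthy control without fractures."""
    return sd.GroupProfile(pore_mode_diameter=27.78, pore_mode_logsd=0.15,
                           tail_fraction=0.10, tail_mode_diameter=80.0,
                           pore_density=250.0)


def analyze_frame(frame, band=(3.0, 9.0)):
    """Standard spectral chain used across tests."""
    surface = se.detect_periosteal_surface(frame)
    ref = se.compute_reference_spectrum(frame, surface, window_mm=2.0)
    spec = se.compute_spectrogram(frame, surface, ref, window_mm=2.0,
                                  overlap=0.75, min_depth_mm=1.0)
    att = se.estimate_attenuation(spec, band)
    bsc = se.estimate_bsc(spec, att)
    return surface, ref, spec, att, bsc


@pytest.fixture(scope="session")
def analyzed_recovery_frame(recovery_acq, control_profile):
    """One simulated + analyzed frame shared by several recovery tests."""
    pop = sd.sample_pore_population(control_profile, 120.0, rng_seed=11)
    frame = sd.simulate_rf_frame(pop, recovery_acq, rng_seed=12,
                                 alpha0=1.5, alphaf=0.10)
    return frame, analyze_frame(frame)
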