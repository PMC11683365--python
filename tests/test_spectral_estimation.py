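import numpy as np
import pytest

from cortbs import spectral_estimation as se
from cortbs import synthetic_data as sd
from cortbs.errors import EstimationError, InputError, NoValidSurfaceError
from cortbs.frames import AcquisitionConfig

from conftest import analyze_frame


def _surface_only_frame(acq, tilt=0.0, seed=0):
    empty = sd.PorePopulation(np.array([]), density=1.0, volume_mm3=0.0)
    return sd.simulate_rf_frame(empty, acq, rng_seed=seed, surface_tilt_deg=tilt)


# --- surface detection ----------------------------------------------------

def test_flat_surface_depth_and_inclination(small_acq):
    frame = _surface_only_frame(small_acq)
    surf = se.detect_periosteal_surface(frame)
    pulse_len_mm = 0.5 * small_acq.speed_of_sound_tissue * 1e3 * 1e-6  # ~0.77 mm
    assert np.all(np.abs(surf.surface_depth_mm - 10.0) < pulse_len_mm / 2)
    assert np.all(np.abs(surf.inclination_deg) < 1.0)
    assert surf.quality_flag.all()


def test_tilted_surface_inclination_recovered():
    acq = AcquisitionConfig(beam_count=24, sweep_count=4, noise_level_db=-80,
                            analysis_depth_mm=6.0, fractional_bandwidth=1.2)
    frame = _surface_only_frame(acq, tilt=8.0)
    surf = se.detect_periosteal_surface(frame, inclination_cutoff_deg=15.0)
    assert abs(np.median(surf.inclination_deg) - 8.0) <= 1.0


def test_noise_only_frame_has_no_valid_surface(small_acq):
    rng = np.random.default_rng(0)
    noise = rng.normal(0, 1.0, size=(small_acq.sweep_count,
                                     small_acq.beam_count,
                                     small_acq.n_samples))
    frame = se.RFFrame(samples=noise, acq=small_acq)
    with pytest.raises(NoValidSurfaceError):
        se.detect_periosteal_surface(frame)


def test_gate_outside_window_rejected(small_acq):
    frame = _surface_only_frame(small_acq)
    with pytest.raises(InputError):
        se.detect_periosteal_surface(frame, gate_mm=(50.0, 80.0))


# --- reference spectrum ---------------------------------------------------

def test_reference_peak_at_center_frequency(small_acq):
    frame = _surface_only_frame(small_acq)
    surf = se.detect_periosteal_surface(frame)
    ref = se.compute_reference_spectrum(frame, surf)
    peak_f = ref.frequencies[np.argmax(ref.amplitude_db)]
    df = ref.frequencies[1] - ref.frequencies[0]
    assert abs(peak_f - small_acq.center_frequency) <= 3 * df
    assert ref.n_beams_used == small_acq.beam_count * small_acq.sweep_count


def test_inclination_correction_inverts_specular_factor():
    """A tilted surface echo (cos-scaled by the simulator) is corrected back
    to the flat-surface reference within 0.1 dB over the band."""
    acq = AcquisitionConfig(beam_count=24, sweep_count=4, noise_level_db=-200,
                            analysis_depth_mm=6.0, fractional_bandwidth=1.2)
    refs = []
    for tilt in (0.0, 10.0):
        frame = _surface_only_frame(acq, tilt=tilt)
        surf = se.detect_periosteal_surface(frame)
        refs.append(se.compute_reference_spectrum(frame, surf))
    band = (refs[0].frequencies >= 3) & (refs[0].frequencies <= 9)
    diff = refs[1].amplitude_db[band] - refs[0].amplitude_db[band]
    assert np.abs(diff).max() < 0.1


def test_zero_quality_beams_raise(small_acq):
    frame = _surface_only_frame(small_acq)
    surf = se.detect_periosteal_surface(frame)
    surf.quality_flag[:] = False
    with pytest.raises(NoValidSurfaceError):
        se.compute_reference_spectrum(frame, surf)


# --- spectrogram ----------------------------------------------------------

def test_normalization_identity_for_delayed_pulse_copy(small_acq):
    """Post-surface content equal to a delayed copy of the pulse gives a
    spectrogram near 0 dB at that depth across the band."""
    frame = _surface_only_frame(small_acq)
    acq = small_acq
    fs = acq.sampling_rate
    surf_sample = 2 * acq.surface_depth_mm * 1e-3 / acq.speed_of_sound_tissue * 1e6 * fs
    depth_mm = 2.0
    delay = 2 * depth_mm * 1e-3 / acq.speed_of_sound_bone * 1e6 * fs
    shift = int(round(delay))
    copied = frame.samples.copy()
    copied[..., :] += np.roll(frame.samples, shift, axis=-1)
    frame2 = se.RFFrame(samples=copied, acq=acq)
    # gate excludes the delayed copy so detection locks onto the true surface
    surf = se.detect_periosteal_surface(frame2, gate_mm=(8.5, 10.5))
    ref = se.compute_reference_spectrum(frame2, surf, window_mm=2.0)
    spec = se.compute_spectrogram(frame2, surf, ref, window_mm=2.0,
                                  overlap=0.75, min_depth_mm=0.5)
    k = np.argmin(np.abs(spec.depth_grid - depth_mm))
    band = (spec.frequencies >= 4) & (spec.frequencies <= 8)
    assert np.abs(spec.power_db[k, band]).max() < 1.0


def test_window_halving_preserves_band_average(analyzed_recovery_frame):
    """Parseval consistency: halving the window length leaves the
    band-and-depth-averaged power within 0.5 dB."""
    frame, (surf, ref, _, _, _) = analyzed_recovery_frame
    out = []
    for wmm in (2.0, 1.0):
        spec = se.compute_spectrogram(frame, surf, ref, window_mm=wmm,
                                      overlap=0.5, min_depth_mm=1.0)
        band = (spec.frequencies >= 3) & (spec.frequencies <= 9)
        out.append((spec.depth_grid.size, spec.power_db[:, band].mean()))
    assert out[1][0] > out[0][0]
    assert abs(out[0][1] - out[1][1]) < 0.5


def test_spectrogram_decay_slope_matches_true_attenuation(analyzed_recovery_frame):
    """Per-frequency dB-vs-depth slope = -2 alpha_true(f) within 10%."""
    frame, (_, _, spec, att, _) = analyzed_recovery_frame
    truth = frame.ground_truth
    band = (att.frequencies >= 4) & (att.frequencies <= 8)
    alpha_true = truth.alpha0 + truth.alphaf * att.frequencies[band]
    rel = np.abs(att.alpha_f_curve[band] - alpha_true) / alpha_true
    assert np.median(rel) < 0.10


# --- attenuation ----------------------------------------------------------

def test_alpha6mhz_definitional_identity():
    freqs = np.linspace(3, 9, 20)
    curve = 1.81 + 0.09 * freqs
    spec = se.NormalizedSpectrogram(
        depth_grid=np.array([1.0, 2.0, 3.0, 4.0]),
        frequencies=freqs,
        power_db=-(2 * curve)[None, :] * np.array([1.0, 2.0, 3.0, 4.0])[:, None],
        window_mm=1.0,
    )
    att = se.estimate_attenuation(spec, (3, 9))
    assert att.alpha0 == pytest.approx(1.81, abs=1e-9)
    assert att.alphaf == pytest.approx(0.09, abs=1e-9)
    assert att.alpha6mhz == pytest.approx(att.alpha0 + 6 * att.alphaf, abs=1e-12)
    assert att.alpha6mhz == pytest.approx(2.35, abs=1e-9)


def test_flat_attenuation_gives_alpha6_equal_alpha0():
    freqs = np.linspace(3, 9, 10)
    depths = np.array([1.0, 2.0, 3.0, 4.0])
    spec = se.NormalizedSpectrogram(depths, freqs,
                                    -2 * 1.5 * depths[:, None]
                                    * np.ones_like(freqs)[None, :],
                                    window_mm=1.0)
    att = se.estimate_attenuation(spec, (3, 9))
    assert att.alphaf == pytest.approx(0.0, abs=1e-9)
    assert att.alpha6mhz == pytest.approx(att.alpha0, abs=1e-9)


def test_attenuation_recovery_on_simulated_frames(analyzed_recovery_frame):
    """alpha0 = 1.5 dB/mm, alphaf = 0.10 dB/MHz/mm recovered within
    +/-0.15 and +/-0.02 on noiseless frames."""
    frame, (_, _, _, att, _) = analyzed_recovery_frame
    assert att.alpha0 == pytest.approx(frame.ground_truth.alpha0, abs=0.15)
    assert att.alphaf == pytest.approx(frame.ground_truth.alphaf, abs=0.02)


def test_too_few_depth_bins_raise():
    freqs = np.linspace(3, 9, 5)
    spec = se.NormalizedSpectrogram(np.array([1.0, 2.0]), freqs,
                                    np.zeros((2, 5)), window_mm=1.0)
    with pytest.raises(EstimationError):
        se.estimate_attenuation(spec, (3, 9))


# --- backscatter ----------------------------------------------------------

def test_zero_attenuation_makes_bsc_equal_aib():
    freqs = np.linspace(3, 9, 10)
    depths = np.array([1.0, 2.0, 3.0, 4.0])
    rng = np.random.default_rng(0)
    power = rng.normal(-14, 0.5, size=(4, 10))
    spec = se.NormalizedSpectrogram(depths, freqs, power, window_mm=1.0)
    att = se.AttenuationResult(freqs, np.zeros(10), 0.0, 0.0, 0.0, 1.0, (3, 9))
    bsc = se.estimate_bsc(spec, att)
    assert bsc.bsc_mean == pytest.approx(bsc.aib_average, abs=1e-12)


def test_constant_field_identity():
    freqs = np.linspace(3, 9, 10)
    depths = np.array([1.0, 2.0, 3.0, 4.0])
    spec = se.NormalizedSpectrogram(depths, freqs, np.full((4, 10), -14.0), 1.0)
    att = se.AttenuationResult(freqs, np.zeros(10), 0.0, 0.0, 0.0, 1.0, (3, 9))
    bsc = se.estimate_bsc(spec, att)
    assert bsc.bsc_mean == pytest.approx(-14.0, abs=1e-12)
    assert bsc.aib_average == pytest.approx(-14.0, abs=1e-12)
    assert bsc.bsc_mean == pytest.approx(np.mean(bsc.bsc_db), abs=1e-12)


def test_band_mismatch_rejected():
    freqs = np.linspace(3, 9, 10)
    depths = np.array([1.0, 2.0, 3.0, 4.0])
    spec = se.NormalizedSpectrogram(depths, freqs, np.zeros((4, 10)), 1.0)
    att = se.AttenuationResult(np.linspace(4, 8, 6), np.zeros(6),
                               0.0, 0.0, 0.0, 1.0, (4, 8))
    with pytest.raises(InputError):
        se.estimate_bsc(spec, att)


def test_aib_never_exceeds_bsc_for_nonnegative_attenuation(analyzed_recovery_frame):
    _, (_, _, _, att, bsc) = analyzed_recovery_frame
    assert np.all(att.alpha_f_curve > 0)
    assert bsc.aib_average <= bsc.bsc_mean


def test_bsc_monotone_in_pore_density(recovery_acq):
    """More scatterers never lower the backscatter amplitude (dilute regime);
    doubling the density raises bsc_mean by ~3 dB (incoherent power)."""
    means = []
    for dens in (60.0, 120.0, 240.0):
        prof = sd.GroupProfile(pore_density=dens, tail_fraction=0.1)
        vals = []
        for seed in (0, 1, 2):
            pop = sd.sample_pore_population(prof, 60.0, rng_seed=seed)
            frame = sd.simulate_rf_frame(pop, recovery_acq, rng_seed=50 + seed)
            *_, bsc = analyze_frame(frame)
            vals.append(bsc.bsc_mean)
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]
    assert means[2] - means[1] == pytest.approx(3.01, abs=0.5)
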