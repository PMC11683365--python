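"""Spectral estimation chain: surface detection, reference spectrum,
normalized depth spectrogram, and attenuation / backscatter coefficients.

The chain mirrors a pulse-echo cortical backscatter measurement:

1. detect the periosteal bone surface (specular echo) and the local beam
   inclination on every A-line, with quality gating;
2. form an inclination-corrected reference spectrum from the surface echoes;
3. slide tapered windows down the cortex to build a depth-dependent power
   spectrogram, expressed in dB relative to the reference;
4. estimate the frequency-dependent attenuation ``alpha(f)`` from the
   dB-vs-depth slopes (round trip: slope = -2 alpha(f)) and summarize it by
   a linear fit ``alpha(f) = alpha0 + alphaf * f``;
5. estimate the backscatter coefficient ``BSC(f)`` by compensating the
   spectrogram for attenuation, together with the apparent integrated
   backscatter (AIB, uncompensated).

Conventions: depth is 0 at the periosteal surface, positive into the bone,
in mm; spectra are power dB; attenuation is reported one-way in dB/mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert
from scipy.signal.windows import hann

from .errors import EstimationError, InputError, NoValidSurfaceError
from .frames import AcquisitionConfig, RFFrame

_N_FFT = 1024

#: Default quality gates (configurable per call): reference-echo SNR and
#: beam-inclination cutoff for the specular amplitude correction.
SNR_THRESHOLD_DB = 20.0
INCLINATION_CUTOFF_DEG = 15.0
MIN_QUALITY_BEAM_FRACTION = 0.25


@dataclass
class SurfaceMap:
    surface_depth_mm: np.ndarray  # (sweep, beam), tissue depth of the surface
    inclination_deg: np.ndarray  # (sweep, beam)
    quality_flag: np.ndarray  # (sweep, beam) bool
    snr_db: np.ndarray  # (sweep, beam)


@dataclass
class ReferenceSpectrum:
    frequencies: np.ndarray  # MHz
    amplitude_db: np.ndarray  # power dB re arbitrary, per frequency
    n_beams_used: int
    window_samples: int


@dataclass
class NormalizedSpectrogram:
    depth_grid: np.ndarray  # mm below the surface (bin centers)
    frequencies: np.ndarray  # MHz
    power_db: np.ndarray  # (depth, frequency), dB relative to the reference
    window_mm: float


@dataclass
class AttenuationResult:
    frequencies: np.ndarray  # MHz (band)
    alpha_f_curve: np.ndarray  # dB/mm per frequency, one-way
    alpha0: float  # dB/mm
    alphaf: float  # dB/MHz/mm
    alpha6mhz: float  # dB/mm, = alpha0 + 6 * alphaf by definition
    fit_r2: float
    band: tuple[float, float]


@dataclass
class BSCResult:
    frequencies: np.ndarray  # MHz
    bsc_db: np.ndarray  # per frequency, attenuation-compensated
    bsc_mean: float  # band average of bsc_db
    aib_average: float  # band-and-depth average WITHOUT compensation
    band: tuple[float, float]


def _depth_to_sample(depth_mm, acq: AcquisitionConfig):
    """Tissue depth [mm] -> sample index (two-way travel)."""
    t_us = 2.0 * np.asarray(depth_mm) * 1e-3 / acq.speed_of_sound_tissue * 1e6
    return t_us * acq.sampling_rate


def detect_periosteal_surface(
    frame: RFFrame,
    gate_mm: tuple[float, float] | None = None,
    *,
    snr_threshold_db: float = SNR_THRESHOLD_DB,
    inclination_cutoff_deg: float = INCLINATION_CUTOFF_DEG,
    min_quality_fraction: float = MIN_QUALITY_BEAM_FRACTION,
) -> SurfaceMap:
    """Detect the periosteal surface and beam inclination on every A-line.

    The surface depth of each line is the envelope maximum inside the gate;
    the inclination comes from a local plane fit to neighboring surface
    depths across beams and sweeps.  Lines with reference-echo SNR below
    ``snr_threshold_db`` or inclination beyond ``inclination_cutoff_deg``
    are flagged out; if fewer than ``min_quality_fraction`` of lines remain,
    a "no valid surface" error is raised.
    """
    acq = frame.acq
    if gate_mm is None:
        gate_mm = (acq.surface_depth_mm - 3.0, acq.surface_depth_mm + 3.0)
    lo = int(np.floor(_depth_to_sample(gate_mm[0], acq)))
    hi = int(np.ceil(_depth_to_sample(gate_mm[1], acq)))
    n_t = frame.samples.shape[-1]
    if lo < 0 or hi > n_t or lo >= hi:
        raise InputError(
            f"gate {gate_mm} mm maps to samples [{lo}, {hi}) outside the "
            f"recorded window of {n_t} samples"
        )

    env = np.abs(hilbert(frame.samples, axis=-1))
    peak_idx = lo + np.argmax(env[..., lo:hi], axis=-1)
    peak_amp = np.take_along_axis(env, peak_idx[..., None], axis=-1)[..., 0]
    c_t = acq.speed_of_sound_tissue
    depth = peak_idx / acq.sampling_rate * 1e-6 * c_t / 2.0 * 1e3  # mm

    # noise floor from the echo-free early part of the record
    n_noise = max(8, int(0.6 * lo))
    noise_rms = np.sqrt(np.mean(frame.samples[..., :n_noise] ** 2,
                                axis=-1)) + 1e-30
    snr = 20.0 * np.log10(peak_amp / noise_rms + 1e-30)
    snr_ok = snr >= snr_threshold_db

    # local plane fit z(x, y) over +/-2 beams and +/-1 sweep
    s_cnt, b_cnt = depth.shape
    x = acq.beam_positions_mm
    y = acq.sweep_positions_mm
    incl = np.zeros_like(depth)
    for s in range(s_cnt):
        for b in range(b_cnt):
            s0, s1 = max(0, s - 1), min(s_cnt, s + 2)
            b0, b1 = max(0, b - 2), min(b_cnt, b + 3)
            ss, bb = np.meshgrid(np.arange(s0, s1), np.arange(b0, b1),
                                 indexing="ij")
            ok = snr_ok[ss, bb]
            if ok.sum() < 3:
                continue
            xs = x[bb[ok]]
            ys = y[ss[ok]]
            zs = depth[ss[ok], bb[ok]]
            a = np.column_stack([np.ones_like(xs), xs, ys])
            coef, *_ = np.linalg.lstsq(a, zs, rcond=None)
            gx, gy = coef[1], coef[2]
            incl[s, b] = np.degrees(np.arctan(np.hypot(gx, gy))) * np.sign(gx or 1.0)

    quality = snr_ok & (np.abs(incl) <= inclination_cutoff_deg)
    if quality.sum() < max(1, min_quality_fraction * quality.size):
        raise NoValidSurfaceError(
            f"no valid surface: only {int(quality.sum())}/{quality.size} lines "
            f"passed SNR >= {snr_threshold_db} dB and |inclination| <= "
            f"{inclination_cutoff_deg} deg"
        )
    return SurfaceMap(surface_depth_mm=depth, inclination_deg=incl,
                      quality_flag=quality, snr_db=snr)


def _window_samples(window_mm: float, acq: AcquisitionConfig) -> int:
    """Bone-depth window length [mm] -> samples (two-way travel)."""
    t_us = 2.0 * window_mm * 1e-3 / acq.speed_of_sound_bone * 1e6
    return max(8, int(round(t_us * acq.sampling_rate)))


def _segment_power_db(segments: np.ndarray, window: np.ndarray) -> np.ndarray:
    """Window-energy-normalized power spectra in dB (last axis = time)."""
    spec = np.fft.rfft(segments * window, n=_N_FFT, axis=-1)
    power = np.abs(spec) ** 2 / np.sum(window**2)
    return power


def compute_reference_spectrum(
    frame: RFFrame,
    surface: SurfaceMap,
    *,
    window_mm: float = 2.0,
) -> ReferenceSpectrum:
    """Inclination-corrected reference spectrum from the surface echoes.

    Each quality beam contributes the windowed power spectrum of its surface
    echo, amplitude-corrected for the specular obliquity factor
    ``1/cos(inclination)``; beams are averaged in dB.  The window length
    matches the spectrogram windows so that window smearing cancels in the
    normalization.
    """
    quality = surface.quality_flag
    if quality.sum() < 1:
        raise NoValidSurfaceError("no quality beam for the reference spectrum")
    acq = frame.acq
    n_w = _window_samples(window_mm, acq)
    win = hann(n_w, sym=False)
    freq = np.fft.rfftfreq(_N_FFT, d=1.0 / acq.sampling_rate)

    idx = np.rint(_depth_to_sample(surface.surface_depth_mm, acq)).astype(int)
    segs, corr_db = [], []
    n_t = frame.samples.shape[-1]
    for s, b in zip(*np.nonzero(quality)):
        c = idx[s, b]
        a, z = c - n_w // 2, c - n_w // 2 + n_w
        if a < 0 or z > n_t:
            continue
        segs.append(frame.samples[s, b, a:z])
        cosg = np.cos(np.deg2rad(surface.inclination_deg[s, b]))
        corr_db.append(-20.0 * np.log10(cosg))
    if not segs:
        raise NoValidSurfaceError("surface echoes fall outside the record")
    power = _segment_power_db(np.asarray(segs), win)
    db = 10.0 * np.log10(power + 1e-300) + np.asarray(corr_db)[:, None]
    return ReferenceSpectrum(frequencies=freq, amplitude_db=db.mean(axis=0),
                             n_beams_used=len(segs), window_samples=n_w)


def compute_spectrogram(
    frame: RFFrame,
    surface: SurfaceMap,
    ref: ReferenceSpectrum,
    *,
    window_mm: float = 2.0,
    overlap: float = 0.75,
    min_depth_mm: float = 1.0,
) -> NormalizedSpectrogram:
    """Normalized depth-dependent spectrogram below the periosteal surface.

    Sliding Hann windows (length ``window_mm`` of bone depth, ``overlap``
    fractional overlap) are applied below the detected surface of every
    quality line; power spectra are averaged over lines in the linear domain
    and expressed in dB relative to the reference spectrum.
    """
    acq = frame.acq
    n_w = _window_samples(window_mm, acq)
    win = hann(n_w, sym=False)
    step = window_mm * (1.0 - overlap)
    d_lo = min_depth_mm + window_mm / 2.0
    d_hi = acq.analysis_depth_mm - window_mm / 2.0
    if d_hi < d_lo:
        raise InputError("analysis depth too shallow for the window length")
    centers = np.arange(d_lo, d_hi + 1e-9, step)

    c_b = acq.speed_of_sound_bone
    n_t = frame.samples.shape[-1]
    surf_idx = _depth_to_sample(surface.surface_depth_mm, acq)
    lines = list(zip(*np.nonzero(surface.quality_flag)))
    power = np.zeros((len(centers), ref.frequencies.size))
    truncated = False
    for k, d in enumerate(centers):
        segs = []
        for s, b in lines:
            c = int(round(surf_idx[s, b]
                          + 2.0 * d * 1e-3 / c_b * 1e6 * acq.sampling_rate))
            a, z = c - n_w // 2, c - n_w // 2 + n_w
            if z > n_t:
                truncated = True
                seg = np.zeros(n_w)
                avail = frame.samples[s, b, a:n_t]
                seg[: avail.size] = avail
            else:
                seg = frame.samples[s, b, a:z]
            segs.append(seg)
        power[k] = _segment_power_db(np.asarray(segs), win).mean(axis=0)
    if truncated:
        warnings.warn("analysis depth exceeds the recorded samples; "
                      "deep windows were zero-padded", stacklevel=2)
    power_db = 10.0 * np.log10(power + 1e-300) - ref.amplitude_db[None, :]
    return NormalizedSpectrogram(depth_grid=centers, frequencies=ref.frequencies,
                                 power_db=power_db, window_mm=window_mm)


def estimate_attenuation(
    spec: NormalizedSpectrogram,
    band: tuple[float, float],
) -> AttenuationResult:
    """Frequency-dependent attenuation from dB-vs-depth regression.

    For each frequency in the band the spectrogram power (dB) is regressed
    on depth; the round-trip slope equals ``-2 alpha(f)``.  ``alpha0`` and
    ``alphaf`` are the intercept and slope of a linear fit of ``alpha(f)``
    over the band, and ``alpha6mhz = alpha0 + 6 alphaf`` by definition.
    """
    if spec.depth_grid.size < 4:
        raise EstimationError(
            f"need >= 4 depth bins for the attenuation fit, got {spec.depth_grid.size}"
        )
    f_lo, f_hi = band
    sel = (spec.frequencies >= f_lo) & (spec.frequencies <= f_hi)
    if sel.sum() < 2:
        raise InputError(f"band {band} MHz not covered by the spectrogram")
    freqs = spec.frequencies[sel]
    depths = spec.depth_grid
    # per-frequency linear regression, vectorized over frequencies
    d_c = depths - depths.mean()
    slopes = d_c @ (spec.power_db[:, sel] - spec.power_db[:, sel].mean(axis=0)) \
        / np.sum(d_c**2)
    alpha_curve = -slopes / 2.0  # one-way dB/mm

    coef = np.polyfit(freqs, alpha_curve, 1)
    alphaf, alpha0 = float(coef[0]), float(coef[1])
    fitted = np.polyval(coef, freqs)
    ss_res = np.sum((alpha_curve - fitted) ** 2)
    ss_tot = np.sum((alpha_curve - alpha_curve.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return AttenuationResult(
        frequencies=freqs,
        alpha_f_curve=alpha_curve,
        alpha0=alpha0,
        alphaf=alphaf,
        alpha6mhz=alpha0 + 6.0 * alphaf,
        fit_r2=float(r2),
        band=(float(f_lo), float(f_hi)),
    )


def estimate_bsc(
    spec: NormalizedSpectrogram,
    att: AttenuationResult,
) -> BSCResult:
    """Backscatter coefficient and AIB from the normalized spectrogram.

    ``bsc_db(f)`` is the depth average of the spectrogram compensated by
    ``+2 alpha(f) * depth`` (round trip); ``bsc_mean`` its band mean.  The
    AIB average is the uncompensated band-and-depth average.
    """
    sel = (spec.frequencies >= att.band[0]) & (spec.frequencies <= att.band[1])
    freqs = spec.frequencies[sel]
    if freqs.size != att.frequencies.size or not np.allclose(freqs, att.frequencies):
        raise InputError("attenuation band does not match the spectrogram band")
    raw = spec.power_db[:, sel]
    comp = raw + 2.0 * att.alpha_f_curve[None, :] * spec.depth_grid[:, None]
    bsc_db = comp.mean(axis=0)
    return BSCResult(
        frequencies=freqs,
        bsc_db=bsc_db,
        bsc_mean=float(bsc_db.mean()),
        aib_average=float(raw.mean()),
        band=att.band,
    )


def bsc_subregions(
    spec: NormalizedSpectrogram,
    att: AttenuationResult,
    n_subregions: int = 2,
) -> list[BSCResult]:
    """Per-depth-subregion BSC estimates (used by the pore-diameter index)."""
    if n_subregions < 1:
        raise InputError("need at least one sub-region")
    splits = np.array_split(np.arange(spec.depth_grid.size), n_subregions)
    out = []
    for part in splits:
        if part.size == 0:
            continue
        sub = NormalizedSpectrogram(
            depth_grid=spec.depth_grid[part],
            frequencies=spec.frequencies,
            power_db=spec.power_db[part],
            window_mm=spec.window_mm,
        )
        out.append(estimate_bsc(sub, att))
    return out
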