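"""Synthetic pore populations, RF frames and cohorts with known ground truth.

Three generators cover the inputs of the analysis chain:

* :func:`sample_pore_population` draws intracortical pore diameters from a
  two-component log-normal mixture (a unimodal "healthy" mode around ~28 um
  plus an optional large-pore "trabecularized" tail), truncated at the 20 um
  resolution floor of the method.
* :func:`simulate_rf_frame` synthesizes pulse-echo A-lines: a specular
  periosteal surface echo (with per-beam inclination), incoherent pore
  echoes filtered by the shared single-pore kernel and attenuated by a
  linear-in-frequency attenuation law, plus additive white noise.
* :func:`synthesize_cohort` draws per-subject parameter tables from
  cell-specific multivariate normals calibrated to the published group
  summaries (see :mod:`cortbs.reference_cohort`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import reference_cohort as ref
from .errors import ConfigurationError, InputError
from .frames import AcquisitionConfig, GroundTruth, RFFrame
from .kernels import backscatter_cross_section

#: Resolution floor of the method: no pore below 20 um is ever generated.
DIAMETER_FLOOR_UM = 20.0


# --- pore populations -----------------------------------------------------

@dataclass(frozen=True)
class GroupProfile:
    """Pore-morphology and attenuation ground truth for one cohort cell."""

    group_label: str = "control"
    fracture_label: str = "nFx"
    pore_mode_diameter: float = 27.78  # um, mode of the main log-normal component
    pore_mode_logsd: float = 0.15
    tail_fraction: float = 0.0  # weight of the large-pore component
    tail_mode_diameter: float = 80.0  # um
    tail_logsd: float = 0.25
    pore_density: float = 150.0  # pores per mm^3
    alpha0_true: float = 1.81  # dB/mm
    alphaf_true: float = 0.09  # dB/MHz/mm

    def validate(self) -> None:
        if self.group_label not in ref.GROUPS:
            raise InputError(f"unknown group label {self.group_label!r}")
        if self.fracture_label not in ref.FRACTURE_LABELS:
            raise InputError(f"unknown fracture label {self.fracture_label!r}")
        if self.pore_mode_diameter < DIAMETER_FLOOR_UM:
            raise InputError("pore mode diameter must be >= 20 um")
        if not 0.0 <= self.tail_fraction <= 1.0:
            raise InputError("tail fraction must lie in [0, 1]")
        if self.pore_density <= 0:
            raise InputError("pore density must be positive")
        if self.tail_mode_diameter <= self.pore_mode_diameter:
            raise InputError("tail mode must exceed the main mode diameter")


@dataclass
class PorePopulation:
    """A sampled ensemble of pore diameters in a simulated region."""

    diameters_um: np.ndarray
    density: float  # pores per mm^3
    volume_mm3: float

    @property
    def count(self) -> int:
        return len(self.diameters_um)


#: The three canonical morphology regimes: healthy unimodal, osteoporotic with
#: a moderate large-pore tail, and "trabecularized" with a heavy tail.
MORPHOLOGY_REGIMES = {
    "healthy": GroupProfile(tail_fraction=0.0),
    "osteoporotic": GroupProfile(tail_fraction=0.25, pore_mode_diameter=30.0),
    "trabecularized": GroupProfile(tail_fraction=0.55, pore_mode_diameter=33.0),
}

#: Per-cell default profiles: main-mode diameters follow the published group
#: peak diameters, tail mass grows with fracture status, and pore density is
#: reduced in the diabetes groups (most strongly in T2DM).  Densities are
#: free parameters of the generator (no published magnitudes exist); the
#: defaults place simulated porosities in the observed single-digit-percent
#: range.
DEFAULT_GROUP_PROFILES = {
    ("control", "nFx"): GroupProfile("control", "nFx", 27.78, 0.15, 0.10, 80.0,
                                     0.25, 250.0, 1.78, 0.10),
    ("control", "Fx"): GroupProfile("control", "Fx", 31.75, 0.15, 0.22, 80.0,
                                    0.25, 250.0, 1.91, 0.05),
    ("T1DM", "nFx"): GroupProfile("T1DM", "nFx", 28.17, 0.15, 0.10, 80.0,
                                  0.25, 180.0, 1.48, 0.13),
    ("T1DM", "Fx"): GroupProfile("T1DM", "Fx", 28.38, 0.15, 0.12, 80.0,
                                 0.25, 250.0, 1.78, 0.12),
    ("T2DM", "nFx"): GroupProfile("T2DM", "nFx", 27.56, 0.15, 0.10, 80.0,
                                  0.25, 150.0, 1.36, 0.13),
    ("T2DM", "Fx"): GroupProfile("T2DM", "Fx", 33.08, 0.15, 0.28, 80.0,
                                 0.25, 150.0, 1.72, 0.06),
}


def _lognormal_from_mode(rng, mode_um, logsd, size):
    # mode of exp(N(mu, s^2)) is exp(mu - s^2) -> mu = ln(mode) + s^2
    mu = np.log(mode_um) + logsd**2
    return rng.lognormal(mean=mu, sigma=logsd, size=size)


def sample_pore_population(
    profile: GroupProfile, volume_mm3: float, rng_seed: int
) -> PorePopulation:
    """Draw a pore population from the profile's diameter mixture.

    Diameters come from a two-component log-normal mixture (main mode at
    ``pore_mode_diameter``, tail at ``tail_mode_diameter`` with weight
    ``tail_fraction``), truncated below the 20 um floor by resampling.
    Reproducible for a given ``rng_seed``.
    """
    profile.validate()
    if volume_mm3 <= 0:
        raise InputError("simulated volume must be positive")
    rng = np.random.default_rng(rng_seed)
    n = int(round(profile.pore_density * volume_mm3))
    diam = np.empty(n)
    remaining = np.arange(n)
    while remaining.size:
        tail = rng.random(remaining.size) < profile.tail_fraction
        d = np.where(
            tail,
            _lognormal_from_mode(rng, profile.tail_mode_diameter,
                                 profile.tail_logsd, remaining.size),
            _lognormal_from_mode(rng, profile.pore_mode_diameter,
                                 profile.pore_mode_logsd, remaining.size),
        )
        diam[remaining] = d
        remaining = remaining[d < DIAMETER_FLOOR_UM]
    return PorePopulation(diameters_um=diam, density=profile.pore_density,
                          volume_mm3=volume_mm3)


# --- RF forward model -----------------------------------------------------

def _pulse_spectrum(freq_mhz: np.ndarray, acq: AcquisitionConfig) -> np.ndarray:
    """Gaussian amplitude spectrum of the emitted pulse (peak 1 at f_c)."""
    sigma = acq.pulse_sigma_mhz()
    return np.exp(-0.5 * ((freq_mhz - acq.center_frequency) / sigma) ** 2)


def simulate_rf_frame(
    population: PorePopulation,
    acq: AcquisitionConfig,
    rng_seed: int,
    *,
    surface_tilt_deg: float = 0.0,
    alpha0: float = 1.5,
    alphaf: float = 0.10,
    depth_pad_mm: float = 1.0,
) -> RFFrame:
    """Simulate one pulse-echo frame for a pore population.

    Each A-line is synthesized in the frequency domain as the sum of

    1. a specular surface echo at the periosteal depth, with amplitude
       ``cos(inclination)`` (the specular obliquity factor);
    2. one echo per pore assigned to that line, spectrally filtered by the
       square root of the shared single-pore backscatter cross-section and
       attenuated round-trip by ``alpha(f) = alpha0 + alphaf * f`` [dB/mm];
    3. additive white Gaussian noise at ``acq.noise_level_db`` relative to
       the surface-echo peak.

    The surface is a plane tilted ``surface_tilt_deg`` across the beam axis.
    Ground truth (surface map, inclinations, attenuation, pores) is attached
    to the returned frame.  RF synthesis is per-beam 1-D (no diffraction);
    inclination enters only through the specular amplitude factor.
    """
    # AcquisitionConfig validates itself on construction (incl. sampling rate).
    rng = np.random.default_rng(rng_seed)
    n_t = acq.n_samples
    freq = np.fft.rfftfreq(n_t, d=1.0 / acq.sampling_rate)  # MHz
    pulse = _pulse_spectrum(freq, acq)
    omega_us = 2.0 * np.pi * freq  # rad per microsecond

    s_cnt, b_cnt = acq.sweep_count, acq.beam_count
    x_beam = acq.beam_positions_mm
    tilt = np.deg2rad(surface_tilt_deg)
    surface_depth = acq.surface_depth_mm + np.tan(tilt) * x_beam  # per beam
    surface_map = np.tile(surface_depth, (s_cnt, 1))
    incl_map = np.full((s_cnt, b_cnt), surface_tilt_deg, dtype=float)

    # assign pores to lines and depths below the surface
    n_pores = population.count
    line_of_pore = rng.integers(0, s_cnt * b_cnt, size=n_pores)
    depth_of_pore = rng.uniform(0.0, acq.analysis_depth_mm + depth_pad_mm,
                                size=n_pores)
    diam = np.asarray(population.diameters_um, dtype=float)

    # per-pore spectral amplitude: sqrt(cross-section) * round-trip attenuation
    alpha_f = alpha0 + alphaf * freq  # dB/mm, one-way
    c_t_mm_us = acq.speed_of_sound_tissue * 1e-3  # mm per us
    c_b_mm_us = acq.speed_of_sound_bone * 1e-3

    spectra = np.zeros((s_cnt * b_cnt, freq.size), dtype=complex)
    cos_incl = np.cos(tilt)
    for s in range(s_cnt):
        for b in range(b_cnt):
            li = s * b_cnt + b
            t_s = 2.0 * surface_depth[b] / c_t_mm_us  # us
            spectra[li] = cos_incl * pulse * np.exp(-1j * omega_us * t_s)
            sel = np.flatnonzero(line_of_pore == li)
            if sel.size:
                z = depth_of_pore[sel]  # mm below surface
                amp = np.sqrt(
                    backscatter_cross_section(freq[:, None], diam[sel][None, :],
                                              sound_speed_bone=acq.speed_of_sound_bone)
                )
                att = 10.0 ** (-(alpha_f[:, None] * 2.0 * z[None, :]) / 20.0)
                phase = np.exp(-1j * omega_us[:, None]
                               * (t_s + 2.0 * z[None, :] / c_b_mm_us))
                spectra[li] += (pulse[:, None] * amp * att * phase).sum(axis=1)

    samples = np.fft.irfft(spectra, n=n_t, axis=1) * n_t / 2.0
    samples = samples.reshape(s_cnt, b_cnt, n_t)

    # noise level relative to the surface-echo peak amplitude
    ref_line = np.fft.irfft(pulse, n=n_t) * n_t / 2.0
    surf_peak = np.abs(ref_line).max() * cos_incl
    noise_rms = surf_peak * 10.0 ** (acq.noise_level_db / 20.0)
    samples = samples + rng.normal(0.0, noise_rms, size=samples.shape)

    truth = GroundTruth(
        surface_depth_mm=surface_map,
        inclination_deg=incl_map,
        alpha0=alpha0,
        alphaf=alphaf,
        pore_diameters_um=diam,
        pore_depths_mm=depth_of_pore,
        pore_density=population.density,
    )
    return RFFrame(samples=samples, acq=acq, ground_truth=truth)


# --- cohort synthesis -----------------------------------------------------

@dataclass
class CellSpec:
    """Sample size, mean vector and SD vector of one group x fracture cell."""

    n: int
    means: dict[str, float]
    sds: dict[str, float]
    male_fraction: float = 0.3


@dataclass
class CohortDesign:
    """Full specification of a synthetic cohort.

    ``correlation`` is shared across cells and must be symmetric positive
    semi-definite with a unit diagonal over ``parameters``.
    """

    cells: dict[tuple[str, str], CellSpec]
    parameters: list[str] = field(default_factory=lambda: list(ref.ALL_PARAMS))
    correlation: np.ndarray | None = None
    clip_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(ref.CLIP_RANGES))
    rng_seed: int = 0
    #: probabilities of (vertebral only, both, other only) among fractured subjects
    fracture_type_probs: tuple[float, float, float] = (11 / 41, 4 / 41, 26 / 41)

    def validate(self) -> None:
        for key, cell in self.cells.items():
            if cell.n < 1:
                raise InputError(f"cell {key} has non-positive size")
            for name in self.parameters:
                if cell.sds.get(name, 0.0) < 0:
                    raise InputError(f"negative SD for {name} in cell {key}")
        if self.correlation is not None:
            corr = np.asarray(self.correlation)
            p = len(self.parameters)
            if corr.shape != (p, p) or not np.allclose(corr, corr.T):
                raise InputError("correlation matrix must be symmetric (p x p)")
            if not np.allclose(np.diag(corr), 1.0):
                raise InputError("correlation matrix must have a unit diagonal")
            eigvals = np.linalg.eigvalsh(corr)
            if eigvals.min() < -1e-10:
                near = nearest_psd(corr)
                raise InputError(
                    "correlation matrix is not positive semi-definite "
                    f"(min eigenvalue {eigvals.min():.3e}); nearest PSD "
                    "correlation obtained by eigenvalue clipping differs by "
                    f"{np.abs(near - corr).max():.3e} (max entry) - consider "
                    "cortbs.synthetic_data.nearest_psd(corr)"
                )


def nearest_psd(corr: np.ndarray) -> np.ndarray:
    """Nearest (in the eigenvalue-clipping sense) PSD correlation matrix."""
    vals, vecs = np.linalg.eigh(np.asarray(corr, dtype=float))
    vals = np.clip(vals, 0.0, None)
    fixed = (vecs * vals) @ vecs.T
    scale = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(scale, scale)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def default_cohort_design(rng_seed: int = 0) -> CohortDesign:
    """Design calibrated to the published per-cell summaries (all effects)."""
    cells = {
        key: CellSpec(
            n=ref.CELL_SIZES[key],
            means={p: ref.CELL_STATS[p][key][0] for p in ref.ALL_PARAMS},
            sds={p: ref.CELL_STATS[p][key][1] for p in ref.ALL_PARAMS},
            male_fraction=ref.MALE_FRACTION[key],
        )
        for key in ref.CELL_SIZES
    }
    return CohortDesign(cells=cells, correlation=ref.default_correlation(),
                        rng_seed=rng_seed)


def headline_effect_design(rng_seed: int = 0) -> CohortDesign:
    """Design in which CortBS carries the fracture signal and DXA the diabetes signal.

    CortBS cell means are fracture-specific (as published); DXA means are
    pooled over fracture within each diabetes group, so any apparent DXA
    fracture discrimination arises only indirectly, through the different
    fracture prevalences of the diabetes groups (the "diabetic paradox").
    """
    design = default_cohort_design(rng_seed)
    for (group, _fx), cell in design.cells.items():
        for p in ref.DXA_PARAMS:
            mean, sd = ref.DXA_GROUP_POOLED[p][group]
            cell.means[p] = mean
            cell.sds[p] = sd
    return design


def synthesize_cohort(design: CohortDesign, rng_seed: int | None = None) -> pd.DataFrame:
    """Draw a per-subject cohort table from the design.

    Rows are drawn cell-wise from a multivariate normal with the cell's mean
    and SD vectors and the shared correlation matrix, then clipped to each
    parameter's plausible range (clip counts are recorded in
    ``df.attrs["clipped"]`` to preserve seed determinism).  Column names are
    the standard CortBS / DXA parameter names.
    """
    design.validate()
    rng = np.random.default_rng(design.rng_seed if rng_seed is None else rng_seed)
    params = design.parameters
    corr = (np.eye(len(params)) if design.correlation is None
            else np.asarray(design.correlation, dtype=float))
    # PSD-safe factor (validate() already rejected genuinely non-PSD input)
    vals, vecs = np.linalg.eigh(corr)
    factor = vecs * np.sqrt(np.clip(vals, 0.0, None))

    rows, clipped = [], {}
    subject = 0
    for (group, fx_label), cell in sorted(design.cells.items()):
        mean = np.array([cell.means[p] for p in params])
        sd = np.array([cell.sds[p] for p in params])
        z = rng.standard_normal((cell.n, len(params)))
        draws = mean + (z @ factor.T) * sd
        for p_i, p in enumerate(params):
            lo, hi = design.clip_ranges.get(p, (-np.inf, np.inf))
            n_clip = int(np.sum((draws[:, p_i] < lo) | (draws[:, p_i] > hi)))
            if n_clip:
                clipped[p] = clipped.get(p, 0) + n_clip
            draws[:, p_i] = np.clip(draws[:, p_i], lo, hi)
        male = rng.random(cell.n) < cell.male_fraction
        for i in range(cell.n):
            row = {
                "subject_id": f"S{subject:04d}",
                "group": group,
                "sex": "M" if male[i] else "F",
                "fracture_any": fx_label == "Fx",
            }
            if row["fracture_any"]:
                u = rng.random()
                p_vert, p_both, _ = design.fracture_type_probs
                row["fracture_vertebral"] = u < p_vert + p_both
                row["fracture_other"] = u >= p_vert
            else:
                row["fracture_vertebral"] = False
                row["fracture_other"] = False
            row.update({p: draws[i, j] for j, p in enumerate(params)})
            rows.append(row)
            subject += 1
    df = pd.DataFrame(rows)
    df.attrs["clipped"] = clipped
    if clipped:
        warnings.warn(f"clipped draws to plausible ranges: {clipped}",
                      stacklevel=2)
    return df
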