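"""RF frame container, acquisition geometry and HDF5 persistence.

An :class:`RFFrame` is a 3-D stack of A-lines (sweep x beam x time sample)
acquired - or simulated - in a pulse-echo geometry: the beam first traverses
soft tissue (speed ``speed_of_sound_tissue``), reflects specularly at the
periosteal bone surface and then probes the cortex (speed
``speed_of_sound_bone``).  Frames produced by the simulator carry their
ground truth alongside the signal so recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .errors import ConfigurationError


@dataclass(frozen=True)
class AcquisitionConfig:
    """Pulse-echo acquisition geometry and pulse definition.

    Frequencies in MHz, depths in mm, speeds in m/s.  ``noise_level_db`` is
    the additive white-noise RMS relative to the periosteal reference-echo
    peak amplitude.
    """

    center_frequency: float = 6.0
    band: tuple[float, float] = (3.0, 9.0)
    sampling_rate: float = 40.0
    speed_of_sound_tissue: float = 1540.0
    speed_of_sound_bone: float = 3565.0
    beam_count: int = 32
    sweep_count: int = 8
    beam_pitch_mm: float = 0.3
    sweep_pitch_mm: float = 0.5
    surface_depth_mm: float = 10.0
    analysis_depth_mm: float = 6.0
    noise_level_db: float = -80.0
    fractional_bandwidth: float = 1.2
    pulse_shape: str = "gaussian"

    def __post_init__(self):
        f_lo, f_hi = self.band
        if not (f_lo < self.center_frequency < f_hi):
            raise ConfigurationError(
                f"band {self.band} must bracket the center frequency "
                f"{self.center_frequency} MHz"
            )
        if self.sampling_rate <= 4.0 * f_hi:
            raise ConfigurationError(
                f"sampling rate {self.sampling_rate} MHz must exceed 4 x f_hi "
                f"= {4.0 * f_hi} MHz"
            )
        if self.analysis_depth_mm <= 0:
            raise ConfigurationError("analysis depth must be positive")
        if self.beam_count < 1 or self.sweep_count < 1:
            raise ConfigurationError("beam and sweep counts must be >= 1")

    # --- derived geometry -------------------------------------------------
    @property
    def beam_positions_mm(self) -> np.ndarray:
        x = np.arange(self.beam_count, dtype=float) * self.beam_pitch_mm
        return x - x.mean()

    @property
    def sweep_positions_mm(self) -> np.ndarray:
        y = np.arange(self.sweep_count, dtype=float) * self.sweep_pitch_mm
        return y - y.mean()

    @property
    def n_samples(self) -> int:
        """Record length covering the surface echo plus the analysis depth."""
        t_surface = 2.0 * (self.surface_depth_mm + 2.0) * 1e-3 / self.speed_of_sound_tissue
        t_bone = 2.0 * (self.analysis_depth_mm + 2.0) * 1e-3 / self.speed_of_sound_bone
        return int(np.ceil((t_surface + t_bone) * self.sampling_rate * 1e6))

    @property
    def time_axis_us(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def pulse_sigma_mhz(self) -> float:
        """Gaussian spectral std of the emitted pulse (FWHM = fractional bandwidth)."""
        return self.fractional_bandwidth * self.center_frequency / 2.3548200450309493


@dataclass
class GroundTruth:
    """Known truth attached to simulated frames."""

    surface_depth_mm: np.ndarray  # (sweep, beam)
    inclination_deg: np.ndarray  # (sweep, beam)
    alpha0: float  # dB/mm
    alphaf: float  # dB/MHz/mm
    pore_diameters_um: np.ndarray
    pore_depths_mm: np.ndarray  # below the surface
    pore_density: float  # pores per mm^3


@dataclass
class RFFrame:
    """3-D pulse-echo channel data with its acquisition geometry."""

    samples: np.ndarray  # (sweep, beam, time)
    acq: AcquisitionConfig
    beam_steering_angles_deg: np.ndarray = field(default=None)
    ground_truth: Optional[GroundTruth] = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 3:
            raise ConfigurationError("samples must be (sweep, beam, time)")
        s, b, t = self.samples.shape
        if b != self.acq.beam_count or s != self.acq.sweep_count:
            raise ConfigurationError(
                f"sample dimensions {self.samples.shape} inconsistent with "
                f"acquisition ({self.acq.sweep_count} sweeps x {self.acq.beam_count} beams)"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ConfigurationError("samples contain non-finite values")
        if self.beam_steering_angles_deg is None:
            self.beam_steering_angles_deg = np.zeros(b)

    @property
    def n_lines(self) -> int:
        return self.samples.shape[0] * self.samples.shape[1]


# --- HDF5 persistence -----------------------------------------------------

def write_rf_hdf5(frame: RFFrame, path) -> None:
    """Write a frame to HDF5 (/rf, /geometry, /ground_truth, config as attrs)."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("rf", data=frame.samples)
        geo = h5.create_group("geometry")
        geo.create_dataset("beam_positions_mm", data=frame.acq.beam_positions_mm)
        geo.create_dataset("sweep_positions_mm", data=frame.acq.sweep_positions_mm)
        geo.create_dataset("beam_steering_angles_deg", data=frame.beam_steering_angles_deg)
        cfg = asdict(frame.acq)
        cfg["band"] = list(cfg["band"])
        for key, val in cfg.items():
            h5.attrs[key] = val
        if frame.ground_truth is not None:
            gt = h5.create_group("ground_truth")
            g = frame.ground_truth
            gt.create_dataset("surface_depth_mm", data=g.surface_depth_mm)
            gt.create_dataset("inclination_deg", data=g.inclination_deg)
            gt.create_dataset("pore_diameters_um", data=g.pore_diameters_um)
            gt.create_dataset("pore_depths_mm", data=g.pore_depths_mm)
            gt.attrs["alpha0"] = g.alpha0
            gt.attrs["alphaf"] = g.alphaf
            gt.attrs["pore_density"] = g.pore_density


def read_rf_hdf5(path) -> RFFrame:
    """Read a frame written by :func:`write_rf_hdf5`."""
    import h5py

    with h5py.File(path, "r") as h5:
        attrs = dict(h5.attrs)
        attrs["band"] = tuple(float(v) for v in attrs["band"])
        for key in ("beam_count", "sweep_count"):
            attrs[key] = int(attrs[key])
        attrs["pulse_shape"] = str(attrs["pulse_shape"])
        for key in list(attrs):
            if key not in AcquisitionConfig.__dataclass_fields__:
                attrs.pop(key)
            elif key not in ("band", "beam_count", "sweep_count", "pulse_shape"):
                attrs[key] = float(attrs[key])
        acq = AcquisitionConfig(**attrs)
        samples = np.asarray(h5["rf"])
        angles = np.asarray(h5["geometry/beam_steering_angles_deg"])
        truth = None
        if "ground_truth" in h5:
            gt = h5["ground_truth"]
            truth = GroundTruth(
                surface_depth_mm=np.asarray(gt["surface_depth_mm"]),
                inclination_deg=np.asarray(gt["inclination_deg"]),
                alpha0=float(gt.attrs["alpha0"]),
                alphaf=float(gt.attrs["alphaf"]),
                pore_diameters_um=np.asarray(gt["pore_diameters_um"]),
                pore_depths_mm=np.asarray(gt["pore_depths_mm"]),
                pore_density=float(gt.attrs["pore_density"]),
            )
    return RFFrame(samples=samples, acq=acq, beam_steering_angles_deg=angles,
                   ground_truth=truth)
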