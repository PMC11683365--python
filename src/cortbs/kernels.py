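"""Single-pore backscatter kernel shared by the forward simulator and the inversion.

The kernel is the single source of truth for how one intracortical pore of
diameter *d* scatters sound at frequency *f*.  Both the RF simulator
(:mod:`cortbs.synthetic_data`) and the pore-size inversion
(:mod:`cortbs.pore_morphology`) import :func:`backscatter_cross_section`, so
forward/inverse self-consistency holds by construction.

Model
-----
A pore is treated as a weak (fluid-like) quasi-cylindrical scatterer at
perpendicular incidence.  In the long-wavelength limit the differential
backscatter cross-section follows the Rayleigh law for cylinders,
``sigma_b ~ d^4 f^3``, multiplied by a Gaussian form factor that rolls the
response off once the wavelength starts to resolve the scatterer::

    sigma_b(f, d) = G * d_mm^4 * f_MHz^3 * exp(-(k * a_eff)^2)

with ``k = 2 pi f / c_bone`` and an *effective* acoustic radius
``a_eff = radius_scale * d / 2``.  ``radius_scale`` (default 4) models the
extended acoustic footprint of a soft inclusion in a stiff matrix; it is the
knob that places the form-factor roll-off of 20-200 um pores inside the
3-9 MHz analysis band, which is what makes the diameter distribution
identifiable from spectral shape.  The constant ``G`` sets the (arbitrary)
relative amplitude scale shared with the reference-normalized measurement.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError

#: Default speed of sound in cortical bone [m/s].
SOUND_SPEED_BONE = 3565.0

#: Effective-radius factor of the Gaussian form-factor roll-off (see module docstring).
RADIUS_SCALE = 4.0

#: Amplitude calibration constant of the kernel (arbitrary relative units).
BACKSCATTER_GAIN = 5.0

#: Maximum k*a_eff for which the kernel is considered valid.
KA_MAX = 8.0


def _ka_eff(freq_mhz, diameter_um, sound_speed_bone, radius_scale):
    k = 2.0 * np.pi * np.asarray(freq_mhz) * 1e6 / sound_speed_bone  # rad/m
    a_eff = radius_scale * np.asarray(diameter_um) * 1e-6 / 2.0  # m
    return k * a_eff


def backscatter_cross_section(
    freq_mhz,
    diameter_um,
    *,
    sound_speed_bone: float = SOUND_SPEED_BONE,
    radius_scale: float = RADIUS_SCALE,
    gain: float = BACKSCATTER_GAIN,
):
    """Backscatter cross-section of a single pore (relative linear power units).

    Parameters broadcast against each other; pass ``freq_mhz`` with shape
    ``(F, 1)`` and ``diameter_um`` with shape ``(D,)`` to obtain an ``(F, D)``
    kernel matrix.
    """
    f = np.asarray(freq_mhz, dtype=float)
    d = np.asarray(diameter_um, dtype=float)
    ka = _ka_eff(f, d, sound_speed_bone, radius_scale)
    d_mm = d * 1e-3
    return gain * d_mm**4 * f**3 * np.exp(-(ka**2))


def kernel_matrix(
    freq_mhz,
    diameter_um,
    *,
    sound_speed_bone: float = SOUND_SPEED_BONE,
    radius_scale: float = RADIUS_SCALE,
    gain: float = BACKSCATTER_GAIN,
    check_validity: bool = True,
):
    """Kernel matrix ``A[f, d]`` over a frequency grid and a diameter grid.

    With ``check_validity`` (the default) frequencies driving any grid
    diameter beyond the kernel's validity limit ``k * a_eff <= KA_MAX`` are
    rejected with an error that states the valid range.
    """
    f = np.atleast_1d(np.asarray(freq_mhz, dtype=float))
    d = np.atleast_1d(np.asarray(diameter_um, dtype=float))
    if check_validity:
        fmax = valid_frequency_limit(
            d.max(), sound_speed_bone=sound_speed_bone, radius_scale=radius_scale
        )
        if np.any(f <= 0) or f.max() > fmax:
            raise InputError(
                "frequencies outside kernel validity: valid range is "
                f"0 < f <= {fmax:.2f} MHz for diameters up to {d.max():.0f} um "
                f"(k*a_eff <= {KA_MAX})"
            )
    return backscatter_cross_section(
        f[:, None],
        d[None, :],
        sound_speed_bone=sound_speed_bone,
        radius_scale=radius_scale,
        gain=gain,
    )


def valid_frequency_limit(
    diameter_um: float,
    *,
    sound_speed_bone: float = SOUND_SPEED_BONE,
    radius_scale: float = RADIUS_SCALE,
) -> float:
    """Largest frequency [MHz] for which a pore of ``diameter_um`` is inside validity."""
    a_eff = radius_scale * diameter_um * 1e-6 / 2.0
    return KA_MAX * sound_speed_bone / (2.0 * np.pi * a_eff) / 1e6
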