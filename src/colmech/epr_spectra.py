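"""Powder EPR spectra from g-tensors, and spectral metrics.

The resonance condition ``B = h nu / (g mu_B)`` maps an orientation-
dependent effective g-factor,

    g(theta, phi)^2 = gx^2 sin^2(theta) cos^2(phi)
                    + gy^2 sin^2(theta) sin^2(phi)
                    + gz^2 cos^2(theta),

onto a resonance field.  The powder pattern is the orientation average
over a deterministic equal-area sphere grid (uniform in cos(theta) and
phi), deposited as a stick histogram on the field axis and convolved with
a Gaussian or Lorentzian line of given peak-to-peak derivative width.
Hyperfine structure is not modelled (unresolved in the target spectra);
field modulation is treated as an ideal first derivative.

Field axes are mT internally; linewidths cross the interface in gauss
(1 mT = 10 G).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .constants import BOHR_MAGNETON, GAUSS_PER_MT, PLANCK_H
from .errors import StructuralError, ValidationError


@dataclass(frozen=True)
class GTensor:
    """Principal g-values.  Axial tensors have gx = gy = g_perp, gz = g_par."""

    gx: float
    gy: float
    gz: float
    sanity_window: tuple[float, float] = (1.5, 2.5)

    def __post_init__(self):
        lo, hi = self.sanity_window
        for g in (self.gx, self.gy, self.gz):
            if not lo < g < hi:
                raise ValidationError(
                    f"g value {g} outside the sanity window ({lo}, {hi})"
                )

    @classmethod
    def isotropic(cls, g: float) -> "GTensor":
        return cls(g, g, g)

    @classmethod
    def axial(cls, g_perp: float, g_par: float) -> "GTensor":
        return cls(g_perp, g_perp, g_par)

    @property
    def g_iso(self) -> float:
        return (self.gx + self.gy + self.gz) / 3.0

    @property
    def is_axial(self) -> bool:
        vals = sorted((self.gx, self.gy, self.gz))
        return (
            np.isclose(vals[0], vals[1], atol=1e-6)
            or np.isclose(vals[1], vals[2], atol=1e-6)
        )

    @property
    def is_isotropic(self) -> bool:
        return np.isclose(self.gx, self.gy, atol=1e-9) and np.isclose(
            self.gy, self.gz, atol=1e-9
        )


@dataclass(frozen=True)
class AcquisitionParams:
    """Sweep and detection settings for a simulated spectrum.

    ``field_min``/``field_max`` of None auto-center the sweep on the
    tensor's resonance fields with a six-linewidth margin.
    """

    frequency_GHz: float = 9.4
    field_min_mT: float | None = None
    field_max_mT: float | None = None
    field_step_mT: float = 0.01
    detection: str = "first_derivative"   # or "absorption"
    lineshape: str = "gaussian"           # or "lorentzian"
    linewidth_pp_G: float = 10.0          # peak-to-peak derivative width
    n_theta: int = 2000
    n_phi: int = 90                       # used only for rhombic tensors

    def __post_init__(self):
        if self.linewidth_pp_G <= 0:
            raise ValidationError("linewidth must be positive")
        if self.field_step_mT <= 0:
            raise ValidationError("field step must be positive")
        if self.detection not in ("first_derivative", "absorption"):
            raise ValidationError(f"unknown detection mode {self.detection!r}")
        if self.lineshape not in ("gaussian", "lorentzian"):
            raise ValidationError(f"unknown lineshape {self.lineshape!r}")
        if self.frequency_GHz <= 0:
            raise ValidationError("frequency must be positive")


@dataclass
class Spectrum:
    field_mT: np.ndarray
    intensity: np.ndarray
    params: AcquisitionParams | None = None

    def __post_init__(self):
        if len(self.field_mT) != len(self.intensity):
            raise StructuralError("field and intensity arrays differ in length")
        if len(self.field_mT) > 1 and not np.all(np.diff(self.field_mT) > 0):
            raise StructuralError("field axis must be strictly increasing")


def resonance_field(g: float, frequency_GHz: float) -> float:
    """Resonance field in mT: B = h nu / (g mu_B)."""
    if g <= 0 or frequency_GHz <= 0:
        raise ValidationError("g and frequency must be positive")
    return PLANCK_H * frequency_GHz * 1e9 / (g * BOHR_MAGNETON) * 1e3


def _line_kernel(field_step: float, width_pp_mT: float, lineshape: str):
    """Unit-area absorption kernel with the requested derivative pp-width."""
    if lineshape == "gaussian":
        sigma = width_pp_mT / 2.0  # derivative extrema of a Gaussian at +-sigma
        half = max(int(np.ceil(6.0 * sigma / field_step)), 2)
        x = np.arange(-half, half + 1) * field_step
        k = np.exp(-0.5 * (x / sigma) ** 2)
    else:
        gamma = np.sqrt(3.0) * width_pp_mT / 2.0  # HWHM; pp = 2 Gamma / sqrt(3)
        half = max(int(np.ceil(40.0 * gamma / field_step)), 2)
        x = np.arange(-half, half + 1) * field_step
        k = 1.0 / (1.0 + (x / gamma) ** 2)
    return k / k.sum()


def powder_spectrum(tensor: GTensor, params: AcquisitionParams) -> Spectrum:
    """Orientation-averaged spectrum of a g-tensor.

    Deterministic equal-area sphere grid (midpoint rule in cos(theta),
    uniform in phi for rhombic tensors); sticks are deposited on the field
    grid with linear charge assignment, then convolved with the lineshape.
    Output is normalized to unit maximum absolute intensity.
    """
    width_mT = params.linewidth_pp_G / GAUSS_PER_MT
    b_principal = sorted(
        resonance_field(g, params.frequency_GHz)
        for g in (tensor.gx, tensor.gy, tensor.gz)
    )
    margin = 6.0 * width_mT
    bmin = params.field_min_mT
    bmax = params.field_max_mT
    if bmin is None:
        bmin = b_principal[0] - margin
    if bmax is None:
        bmax = b_principal[-1] + margin
    if bmin > b_principal[0] - 1e-9:
        raise ValidationError(
            f"field range misses the low-field edge at {b_principal[0]:.3f} mT"
        )
    if bmax < b_principal[-1] + 1e-9:
        raise ValidationError(
            f"field range misses the high-field edge at {b_principal[-1]:.3f} mT"
        )

    field = np.arange(bmin, bmax + params.field_step_mT / 2, params.field_step_mT)

    # orientation grid
    cos_t = (np.arange(params.n_theta) + 0.5) / params.n_theta  # (0, 1)
    sin2 = 1.0 - cos_t**2
    if tensor.is_isotropic:
        g_eff = np.full(1, tensor.gx)
    elif np.isclose(tensor.gx, tensor.gy, atol=1e-9):
        g_eff = np.sqrt(tensor.gx**2 * sin2 + tensor.gz**2 * cos_t**2)
    else:
        phi = (np.arange(params.n_phi) + 0.5) * (np.pi / 2.0) / params.n_phi
        g2 = (
            (tensor.gx**2 * np.cos(phi) ** 2 + tensor.gy**2 * np.sin(phi) ** 2)[
                None, :
            ]
            * sin2[:, None]
            + (tensor.gz**2 * cos_t**2)[:, None]
        )
        g_eff = np.sqrt(g2).ravel()

    b_res = resonance_field(1.0, params.frequency_GHz) / g_eff
    # linear charge assignment of each stick onto the field grid
    pos = (b_res - field[0]) / params.field_step_mT
    lo = np.floor(pos).astype(int)
    frac = pos - lo
    sticks = np.zeros(len(field) + 1)
    np.add.at(sticks, np.clip(lo, 0, len(field) - 1), 1.0 - frac)
    np.add.at(sticks, np.clip(lo + 1, 0, len(field)), frac)
    sticks = sticks[: len(field)] / len(g_eff)

    kernel = _line_kernel(params.field_step_mT, width_mT, params.lineshape)
    # explicit centered slice of the full convolution: np.convolve(..., "same")
    # silently returns the *kernel* length when the kernel outgrows the sweep
    half = (len(kernel) - 1) // 2
    absorption = np.convolve(sticks, kernel, mode="full")[half:half + len(field)]

    if params.detection == "absorption":
        intensity = absorption
    else:
        intensity = np.gradient(absorption, field)
    peak = np.max(np.abs(intensity))
    if peak > 0:
        intensity = intensity / peak
    return Spectrum(field_mT=field, intensity=intensity, params=params)


# ---------------------------------------------------------------------------
# spectral metrics
# ---------------------------------------------------------------------------

def signal_size(spectrum: Spectrum) -> float:
    """cw-EPR signal size: maximal minus minimal intensity."""
    if len(spectrum.intensity) == 0:
        raise ValidationError("empty spectrum")
    return float(spectrum.intensity.max() - spectrum.intensity.min())


def _derivative_extrema(spectrum: Spectrum) -> tuple[int, int]:
    imax = int(np.argmax(spectrum.intensity))
    imin = int(np.argmin(spectrum.intensity))
    if imax >= imin:
        raise ValidationError(
            "spectrum does not look like a single first-derivative line "
            "(positive lobe must precede negative lobe)"
        )
    return imax, imin


def effective_g(spectrum: Spectrum, frequency_GHz: float) -> float:
    """g-factor from the zero-crossing field between the derivative extrema."""
    imax, imin = _derivative_extrema(spectrum)
    y = spectrum.intensity
    b = spectrum.field_mT
    for k in range(imax, imin):
        if y[k] >= 0.0 > y[k + 1]:
            b0 = b[k] + (b[k + 1] - b[k]) * y[k] / (y[k] - y[k + 1])
            return PLANCK_H * frequency_GHz * 1e9 / (BOHR_MAGNETON * b0 * 1e-3)
    raise ValidationError("no zero-crossing between the derivative extrema")


def peak_to_peak_width(spectrum: Spectrum) -> float:
    """Field separation of the derivative extrema, in gauss."""
    imax, imin = _derivative_extrema(spectrum)
    return float(
        (spectrum.field_mT[imin] - spectrum.field_mT[imax]) * GAUSS_PER_MT
    )


def double_integral(spectrum: Spectrum) -> float:
    """Double integral of a first-derivative spectrum (spin-count measure)."""
    first = cumulative_trapezoid(
        spectrum.intensity, spectrum.field_mT, initial=0.0
    )
    return float(np.trapezoid(first, spectrum.field_mT))


def spin_count(
    spectrum: Spectrum, reference: Spectrum, reference_spins: float
) -> float:
    """Spins in ``spectrum`` relative to a reference of known spin count,
    via the ratio of double integrals.  Field axes must match exactly."""
    if len(spectrum.field_mT) != len(reference.field_mT) or not np.allclose(
        spectrum.field_mT, reference.field_mT
    ):
        raise StructuralError("sample and reference field axes differ")
    ref = double_integral(reference)
    if ref <= 0:
        raise ValidationError("reference double integral must be positive")
    return reference_spins * double_integral(spectrum) / ref


def smooth_series(
    values: np.ndarray, stiffness: float, x: np.ndarray | None = None
) -> np.ndarray:
    """Cubic smoothing spline of a series (larger stiffness = smoother)."""
    from scipy.interpolate import make_smoothing_spline

    values = np.asarray(values, dtype=float)
    if x is None:
        x = np.arange(len(values), dtype=float)
    spline = make_smoothing_spline(x, values, lam=stiffness)
    return spline(x)
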