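"""Optical-trap calibration and tether-force / membrane-tension mechanics.

A bead held in an optical trap and attached to a membrane nanotube reports
the apparent membrane tension of the cell. The chain is:

1. the trap stiffness k is calibrated from the thermal fluctuation spectrum
   of the bead (power-spectrum method): the one-sided PSD of an overdamped
   bead is the Lorentzian S(f) = D / (fc^2 + f^2), whose corner frequency
   fc = k / (2 pi zeta) yields k once the drag zeta is known (Stokes drag
   for a sphere in the medium);
2. the tether force is the trap restoring force F0 = k * dx, with dx the
   mean displacement of the bead from the trap center while holding the
   tether;
3. the apparent membrane tension follows from the tether force through
   T = F0^2 / (8 pi^2 B), with B the membrane bending stiffness.

"Apparent" (or "effective") membrane tension is deliberate: in cells the
number conflates in-plane bilayer tension and membrane-cytoskeleton
adhesion, which a tether pull cannot separate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import optimize, signal

from .errors import FitQualityError, ParameterError
from .synthetic import BeadTrajectory

__all__ = [
    "PowerSpectrum",
    "TrapCalibration",
    "TetherMeasurement",
    "compute_psd",
    "fit_lorentzian",
    "zeta_from_stokes",
    "tether_force",
    "tension_from_tether",
    "tether_force_from_tension",
]

#: conventional plasma-membrane bending stiffness, pN*nm (~19-20 kBT at 37 C)
DEFAULT_BENDING_STIFFNESS_PNNM = 81.0
DEFAULT_BEAD_RADIUS_NM = 500.0
DEFAULT_VISCOSITY_MPAS = 1.0


@dataclass
class PowerSpectrum:
    """One-sided, block-averaged power spectral density of bead motion."""

    freq_hz: np.ndarray
    psd: np.ndarray  # nm^2/Hz
    n_blocks: int

    def __post_init__(self):
        if np.any(self.freq_hz <= 0) or np.any(np.diff(self.freq_hz) <= 0):
            raise ParameterError("frequencies must be positive and increasing")
        if np.any(self.psd < 0):
            raise ParameterError("PSD must be nonnegative")

    def total_power(self) -> float:
        """Integral of the one-sided PSD (should approximate the variance)."""
        df = self.freq_hz[1] - self.freq_hz[0]
        return float(np.sum(self.psd) * df)


@dataclass
class TrapCalibration:
    """Result of the Lorentzian fit: corner frequency and trap stiffness."""

    fc_hz: float
    D_plateau: float  # low-frequency plateau S(0) = D / fc^2, nm^2/Hz
    k_trap: float  # pN/nm, = 2 pi zeta fc
    zeta: float  # pN*s/nm
    fit_range_hz: tuple[float, float]
    rms_residual: float  # rms of log-spectrum residuals

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


@dataclass
class TetherMeasurement:
    """A tether pull: displacement, force and apparent tension."""

    f0_pn: float
    dx_nm: float
    k_trap: float
    B_pnnm: float
    tension_pn_per_nm: float

    @classmethod
    def from_displacement(
        cls, dx_nm: float, k_trap: float, B_pnnm: float = DEFAULT_BENDING_STIFFNESS_PNNM
    ) -> "TetherMeasurement":
        f0 = tether_force(dx_nm, k_trap)
        return cls(
            f0_pn=f0,
            dx_nm=dx_nm,
            k_trap=k_trap,
            B_pnnm=B_pnnm,
            tension_pn_per_nm=tension_from_tether(f0, B_pnnm),
        )


def compute_psd(traj: BeadTrajectory, n_blocks: int = 32) -> PowerSpectrum:
    """Block-averaged one-sided periodogram of a bead trajectory.

    The trajectory is cut into ``n_blocks`` non-overlapping segments
    (boxcar window, per-block mean removed); periodograms are averaged.
    The DC bin is always excluded.
    """
    if n_blocks < 1:
        raise ParameterError("n_blocks must be >= 1")
    n = len(traj)
    if n < 2 * n_blocks:
        raise ParameterError(
            f"trajectory of {n} samples too short for {n_blocks} blocks"
        )
    nperseg = n // n_blocks
    freq, psd = signal.welch(
        traj.x_nm,
        fs=traj.fs_hz,
        window="boxcar",
        nperseg=nperseg,
        noverlap=0,
        detrend="constant",
        scaling="density",
    )
    return PowerSpectrum(freq_hz=freq[1:], psd=psd[1:], n_blocks=n_blocks)


def _guess_fc(spec: PowerSpectrum) -> float:
    """Moment estimate of the corner frequency.

    For a Lorentzian D/(fc^2+f^2), total one-sided power is pi D/(2 fc)
    and the plateau is S(0) = D/fc^2, so fc = 2 P / (pi S(0)). Both P and
    S(0) are robustly estimable without knowing fc.
    """
    plateau = float(np.median(spec.psd[: max(5, spec.psd.size // 50)]))
    if plateau <= 0:
        return float(spec.freq_hz[spec.freq_hz.size // 2])
    power = spec.total_power()
    fc = 2.0 * power / (math.pi * plateau)
    return float(np.clip(fc, spec.freq_hz[0], spec.freq_hz[-1]))


def fit_lorentzian(
    psd: PowerSpectrum,
    fit_range_hz: tuple[float, float] | None = None,
    zeta: float | None = None,
    radius_nm: float = DEFAULT_BEAD_RADIUS_NM,
    viscosity_mpas: float = DEFAULT_VISCOSITY_MPAS,
) -> TrapCalibration:
    """Fit S(f) = D / (fc^2 + f^2) and derive the trap stiffness.

    The fit is ordinary least squares on log S(f) over ``fit_range_hz``
    (default: 10 Hz to 3x a moment-based corner-frequency guess, clipped
    to the spectrum support); log-domain fitting tames the multiplicative
    scatter of periodogram estimates. The drag ``zeta`` may be supplied
    directly or derived from Stokes drag for the bead.

    Raises :class:`FitQualityError` when the fit does not converge or the
    fitted corner frequency sits at a boundary of the fit range (the
    symptom of a fit window that excludes the true corner).
    """
    if zeta is None:
        zeta = zeta_from_stokes(radius_nm, viscosity_mpas)
    if fit_range_hz is None:
        fc_guess = _guess_fc(psd)
        # band up to ~3 fc balances leverage on plateau and roll-off against
        # aliasing bias near Nyquist (no aliasing correction is applied)
        fit_range_hz = (
            max(10.0, float(psd.freq_hz[0])),
            min(3.0 * fc_guess, 0.9 * float(psd.freq_hz[-1])),
        )
    lo, hi = fit_range_hz
    sel = (psd.freq_hz >= lo) & (psd.freq_hz <= hi) & (psd.psd > 0)
    if sel.sum() < 10:
        raise ParameterError("need at least 10 positive PSD bins in fit range")
    f = psd.freq_hz[sel]
    logS = np.log(psd.psd[sel])

    def resid(p):
        logD, logfc = p
        return logD - np.log(np.exp(2 * logfc) + f * f) - logS

    fc0 = math.sqrt(lo * hi)
    D0 = float(np.exp(logS[0])) * (fc0**2 + f[0] ** 2)
    sol = optimize.least_squares(resid, x0=[math.log(D0), math.log(fc0)])
    if not sol.success:
        raise FitQualityError(
            "Lorentzian fit did not converge",
            diagnostics={"fit_range_hz": (lo, hi), "status": sol.status},
        )
    D = math.exp(sol.x[0])
    fc = math.exp(sol.x[1])
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    if not (1.05 * lo < fc < hi / 1.05):
        raise FitQualityError(
            f"fitted corner frequency {fc:.3g} Hz sits at the fit-range "
            f"boundary ({lo:.3g}, {hi:.3g}) Hz — widen or recenter the range",
            diagnostics={"fc_hz": fc, "fit_range_hz": (lo, hi), "rms_residual": rms},
        )
    return TrapCalibration(
        fc_hz=fc,
        D_plateau=D / fc**2,
        k_trap=2.0 * math.pi * zeta * fc,
        zeta=zeta,
        fit_range_hz=(lo, hi),
        rms_residual=rms,
    )


def zeta_from_stokes(radius_nm: float, viscosity_mpas: float) -> float:
    """Stokes drag zeta = 6 pi eta r for a sphere, in pN*s/nm.

    1 mPa*s * 1 nm = 1e-3 N s/m^2 * 1e-9 m = 1e-12 N*s/m = 1e-21 pN*s/nm*...
    Unit algebra collapses to zeta[pN*s/nm] = 6 pi * eta[mPa*s] * r[nm] * 1e-12.
    """
    if radius_nm < 0 or viscosity_mpas < 0:
        raise ParameterError("radius and viscosity must be >= 0")
    return 6.0 * math.pi * viscosity_mpas * radius_nm * 1e-12 * 1e3


def tether_force(dx_nm: float, k_trap: float) -> float:
    """Tether force magnitude F0 = k_trap * |dx| (pN)."""
    if k_trap <= 0:
        raise ParameterError("k_trap must be > 0")
    return k_trap * abs(dx_nm)


def tension_from_tether(f0_pn: float, B_pnnm: float) -> float:
    """Apparent membrane tension T = F0^2 / (8 pi^2 B), pN/nm.

    In cells this conflates in-plane tension with membrane-cytoskeleton
    adhesion; report B alongside any tension value.
    """
    if B_pnnm <= 0:
        raise ParameterError("bending stiffness B must be > 0")
    if f0_pn < 0:
        raise ParameterError("tether force must be >= 0")
    return f0_pn**2 / (8.0 * math.pi**2 * B_pnnm)


def tether_force_from_tension(T: float, B_pnnm: float) -> float:
    """Inverse of :func:`tension_from_tether`: F0 = 2 pi sqrt(2 B T)."""
    if B_pnnm <= 0:
        raise ParameterError("bending stiffness B must be > 0")
    if T < 0:
        raise ParameterError("tension must be >= 0")
    return 2.0 * math.pi * math.sqrt(2.0 * B_pnnm * T)
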