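"""Synthetic inputs with known ground truth.

Every downstream stage of the package (trap calibration, uptake
quantification, punctae counting, reservoir-decay fitting) is exercised
against data produced here, so each generator records the truth it used:
an overdamped bead in a harmonic optical trap (exact Ornstein-Uhlenbeck
discretization), wide-field cell fields with per-cell deposited uptake
signal, TIRF-like punctae frames, and exponential reservoir-decay traces.

All generators take an explicit integer seed and are bit-reproducible;
there is no hidden global RNG state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import ParameterError, PlacementError

__all__ = [
    "BeadTrajectory",
    "CellFieldTruth",
    "PunctaeStackTruth",
    "DecayTrace",
    "gen_bead_trajectory",
    "gen_cell_field",
    "gen_punctae_stack",
    "gen_decay_traces",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class BeadTrajectory:
    """Sampled displacement x(t) of a trapped bead.

    time_s is a uniform grid; fs_hz = 1/dt. ``meta`` carries the true
    (k, zeta, kBT) when the trajectory is synthetic.
    """

    time_s: np.ndarray
    x_nm: np.ndarray
    fs_hz: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.x_nm = np.asarray(self.x_nm, dtype=float)
        if self.time_s.size < 2:
            raise ParameterError("trajectory needs at least 2 samples")
        dt = np.diff(self.time_s)
        if np.any(dt <= 0):
            raise ParameterError("time grid must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > 1e-9 * dt[0]:
            raise ParameterError("time grid must be uniform")
        if abs(self.fs_hz * dt[0] - 1.0) > 1e-6:
            raise ParameterError("fs_hz inconsistent with time grid")

    def __len__(self) -> int:
        return self.x_nm.size

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.time_s, "x_nm": self.x_nm}).to_csv(
            path, index=False
        )
        if self.meta:
            Path(path).with_suffix(".json").write_text(json.dumps(self.meta))

    @classmethod
    def from_csv(cls, path: str | Path) -> "BeadTrajectory":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        meta = {}
        sidecar = Path(path).with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return cls(t, df["x_nm"].to_numpy(), fs_hz=1.0 / (t[1] - t[0]), meta=meta)


@dataclass
class CellFieldTruth:
    """A wide-field uptake image plus the truth used to paint it."""

    image: np.ndarray  # 2-D float intensities (16-bit range)
    labels: np.ndarray  # 0 = background, k > 0 = cell k
    true_intensity: pd.DataFrame  # columns: cell_id, true_total
    noise_sd: float
    background: float = 0.0

    def __post_init__(self):
        if self.image.shape != self.labels.shape:
            raise ParameterError("image and label mask shapes differ")
        if np.any(self.labels < 0):
            raise ParameterError("labels must be nonnegative")
        present = set(np.unique(self.labels)) - {0}
        if set(self.true_intensity["cell_id"]) - present:
            raise ParameterError("truth table lists a label absent from mask")


@dataclass
class PunctaeStackTruth:
    """TIRF-like frames with known spot counts and centers."""

    frames: np.ndarray  # (frame, y, x)
    true_counts: list[int]
    true_coords: list[np.ndarray]  # per frame, (n, 2) (row, col)
    psf_sigma_px: float
    snr: float

    def __post_init__(self):
        for f, (c, xy) in enumerate(zip(self.true_counts, self.true_coords)):
            if c != len(xy):
                raise ParameterError(f"frame {f}: count != number of coords")


@dataclass
class DecayTrace:
    """Reservoir-intensity decay I(t) with optional known rate."""

    time_s: np.ndarray
    intensity: np.ndarray
    true_rate: float | None = None
    noise_sd: float = 0.0

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.time_s) <= 0):
            raise ParameterError("time must be increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ParameterError("intensity must be finite")


# ---------------------------------------------------------------------------
# generators


def _require_positive(**kwargs: float) -> None:
    for name, val in kwargs.items():
        if not (val > 0):
            raise ParameterError(f"{name} must be > 0, got {val!r}")


def gen_bead_trajectory(
    k: float,
    zeta: float,
    kBT: float,
    fs: float,
    duration: float,
    seed: int,
) -> BeadTrajectory:
    """Simulate an overdamped bead in a harmonic trap.

    Uses the exact discretization of the Ornstein-Uhlenbeck process,

        x[n+1] = x[n] e^(-dt/tau) + sigma sqrt(1 - e^(-2 dt/tau)) eta[n],

    with relaxation time tau = zeta/k and stationary variance
    sigma^2 = kBT/k (equipartition). The stationary power spectrum is the
    Lorentzian kBT / (pi^2 zeta (fc^2 + f^2)) with corner frequency
    fc = k / (2 pi zeta), which is what the calibration stage recovers.

    Parameters
    ----------
    k : trap stiffness, pN/nm
    zeta : drag coefficient, pN*s/nm
    kBT : thermal energy, pN*nm (>= 0; 0 gives the noiseless limit)
    fs : sampling rate, Hz
    duration : total time, s
    seed : RNG seed
    """
    _require_positive(k=k, zeta=zeta, fs=fs, duration=duration)
    if kBT < 0:
        raise ParameterError("kBT must be >= 0")
    n = int(round(fs * duration))
    if n < 2:
        raise ParameterError("fs * duration must give at least 2 samples")
    dt = 1.0 / fs
    tau = zeta / k
    a = np.exp(-dt / tau)
    sigma = np.sqrt(kBT / k)
    rng = np.random.default_rng(seed)
    # x[0] drawn from the stationary distribution; AR(1) via lfilter
    innov = sigma * np.sqrt(1.0 - a * a) * rng.standard_normal(n - 1)
    x0 = sigma * rng.standard_normal()
    x = np.empty(n)
    x[0] = x0
    x[1:] = lfilter([1.0], [1.0, -a], innov) + x0 * a ** np.arange(1, n)
    t = np.arange(n) * dt
    return BeadTrajectory(
        t, x, fs_hz=fs, meta={"k": k, "zeta": zeta, "kBT": kBT, "seed": seed}
    )


def _place_nonoverlapping(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    radii: np.ndarray,
    margin: float,
    max_tries: int,
) -> np.ndarray:
    """Rejection-sample n centers so circles of given radii do not overlap."""
    centers: list[tuple[float, float]] = []
    for i in range(n):
        r = radii[i]
        for _ in range(max_tries):
            cy = rng.uniform(r + margin, shape[0] - r - margin)
            cx = rng.uniform(r + margin, shape[1] - r - margin)
            ok = all(
                np.hypot(cy - y0, cx - x0) > r + radii[j] + margin
                for j, (y0, x0) in enumerate(centers)
            )
            if ok:
                centers.append((cy, cx))
                break
        else:
            raise PlacementError(
                f"could not place object {i + 1}/{n} in shape {shape} "
                f"after {max_tries} tries"
            )
    return np.array(centers).reshape(n, 2)


def gen_cell_field(
    n_cells: int,
    mean_uptake: float = 5e4,
    cv: float = 0.3,
    noise_sd: float = 2.0,
    shape: tuple[int, int] = (512, 512),
    seed: int = 0,
    background: float = 100.0,
) -> CellFieldTruth:
    """Paint a wide-field image of cells with endocytosed signal.

    Cells are non-overlapping ellipses. Each cell's total deposited signal
    is drawn log-normally with the requested mean and coefficient of
    variation (uptake per cell is positive and right-skewed), spread over
    intra-cell puncta plus a diffuse component, then a constant background
    offset and additive Gaussian camera noise are applied. The per-cell
    pixel sum over the mask equals the drawn truth exactly before noise.
    """
    if n_cells < 0:
        raise ParameterError("n_cells must be >= 0")
    if cv < 0 or noise_sd < 0:
        raise ParameterError("cv and noise_sd must be >= 0")
    _require_positive(mean_uptake=mean_uptake)
    rng = np.random.default_rng(seed)
    image = np.full(shape, float(background))
    labels = np.zeros(shape, dtype=np.int32)
    rows = []
    if n_cells > 0:
        semi_major = rng.uniform(14, 22, n_cells)
        centers = _place_nonoverlapping(
            rng, n_cells, shape, semi_major, margin=3.0, max_tries=500
        )
        if cv > 0:
            s2 = np.log1p(cv * cv)
            totals = rng.lognormal(
                mean=np.log(mean_uptake) - s2 / 2.0, sigma=np.sqrt(s2), size=n_cells
            )
        else:
            totals = np.full(n_cells, mean_uptake)
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        for i in range(n_cells):
            cy, cx = centers[i]
            a = semi_major[i]
            b = rng.uniform(0.6, 1.0) * a
            theta = rng.uniform(0, np.pi)
            dy, dx = yy - cy, xx - cx
            u = dy * np.cos(theta) + dx * np.sin(theta)
            w = -dy * np.sin(theta) + dx * np.cos(theta)
            mask = (u / a) ** 2 + (w / b) ** 2 <= 1.0
            labels[mask] = i + 1
            # intra-cell texture: diffuse base + a few bright puncta,
            # renormalized so the masked sum equals the drawn total exactly
            pattern = np.zeros(shape)
            pattern[mask] = 1.0
            n_puncta = rng.integers(5, 12)
            my, mx = np.nonzero(mask)
            pick = rng.integers(0, my.size, n_puncta)
            for py, px in zip(my[pick], mx[pick]):
                g = np.exp(-((yy - py) ** 2 + (xx - px) ** 2) / (2 * 2.0**2))
                pattern += 8.0 * g * mask
            pattern *= totals[i] / pattern.sum()
            image += pattern
            rows.append({"cell_id": i + 1, "true_total": totals[i]})
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, shape)
    truth = pd.DataFrame(rows, columns=["cell_id", "true_total"])
    return CellFieldTruth(
        image=image,
        labels=labels,
        true_intensity=truth,
        noise_sd=noise_sd,
        background=background,
    )


def gen_punctae_stack(
    counts_per_frame: list[int],
    psf_sigma_px: float = 1.5,
    snr: float = 10.0,
    shape: tuple[int, int] = (128, 128),
    seed: int = 0,
    amplitude: float = 100.0,
) -> PunctaeStackTruth:
    """Render frames of diffraction-limited spots at known positions.

    Spots are isotropic Gaussians of width ``psf_sigma_px`` placed with
    pairwise separation >= 4 sigma; the background noise s.d. is set to
    amplitude/snr so ``snr`` is the peak-to-noise ratio.
    """
    _require_positive(psf_sigma_px=psf_sigma_px, snr=snr)
    if any(c < 0 for c in counts_per_frame):
        raise ParameterError("spot counts must be >= 0")
    rng = np.random.default_rng(seed)
    noise_sd = amplitude / snr
    min_sep = 4.0 * psf_sigma_px
    edge = 3.0 * psf_sigma_px
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    frames = []
    coords_all: list[np.ndarray] = []
    for c in counts_per_frame:
        frame = np.zeros(shape)
        if c > 0:
            radii = np.full(c, min_sep / 2.0)
            try:
                centers = _place_nonoverlapping(
                    rng, c, shape, radii, margin=edge - min_sep / 2.0, max_tries=500
                )
            except PlacementError as err:
                raise PlacementError(
                    f"cannot place {c} spots at separation {min_sep:.1f} px "
                    f"in frame {shape}"
                ) from err
            for cy, cx in centers:
                frame += amplitude * np.exp(
                    -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * psf_sigma_px**2)
                )
            coords_all.append(centers)
        else:
            coords_all.append(np.empty((0, 2)))
        frame += rng.normal(0.0, noise_sd, shape)
        frames.append(frame)
    return PunctaeStackTruth(
        frames=np.stack(frames),
        true_counts=[len(c) for c in coords_all],
        true_coords=coords_all,
        psf_sigma_px=psf_sigma_px,
        snr=snr,
    )


def gen_decay_traces(
    I0: float,
    rate: float,
    noise_sd: float,
    n: int,
    t_end: float,
    seed: int,
    n_points: int = 60,
) -> list[DecayTrace]:
    """Exponential reservoir-intensity decays I(t) = I0 e^(-rate t) + noise."""
    _require_positive(I0=I0, t_end=t_end)
    if rate < 0 or noise_sd < 0 or n < 1:
        raise ParameterError("rate, noise_sd must be >= 0 and n >= 1")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, t_end, n_points)
    clean = I0 * np.exp(-rate * t)
    traces = []
    for _ in range(n):
        noisy = clean + (rng.normal(0.0, noise_sd, t.size) if noise_sd > 0 else 0.0)
        traces.append(
            DecayTrace(time_s=t, intensity=noisy, true_rate=rate, noise_sd=noise_sd)
        )
    return traces
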