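"""MSD-based diffusion analysis of single-molecule tracks.

Each track's time-averaged mean-squared displacement,

    MSD(tau) = (1/N_tau) * sum_i [r(t_i) - r(t_i + tau)]^2,

is fitted over its first few lags with the 2D free-diffusion line
``MSD = 4*D*tau + b``, where the intercept ``b = -4*D*dt/3 + 4*sigma^2``
collects the dynamic error from motion blur during the exposure (negative
term) and the static localization error (positive term). Per-track D values
are summarized as mean +/- SEM, and their histogram can be decomposed into
one or two Gaussian mobility populations. The module also implements the
adaptive maximum-linking-radius rule used to parameterize particle linking
from a preliminary diffusion estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

DT_DEFAULT = 0.0217        # s, frame interval
PIXEL_SIZE_DEFAULT = 0.160  # µm
MIN_FIT_LENGTH = 12        # frames required for diffusion fitting


@dataclass
class Track:
    """Gapless time-ordered 2D positions of one molecule, µm."""

    frames: np.ndarray  # consecutive integer frame indices
    xy: np.ndarray      # (n, 2) positions, µm
    dt: float = DT_DEFAULT

    def __post_init__(self):
        self.frames = np.asarray(self.frames, int)
        self.xy = np.asarray(self.xy, float)
        if len(self.frames) != len(self.xy):
            raise ValueError("frames and xy must have equal length")
        if len(self.frames) >= 2 and np.any(np.diff(self.frames) != 1):
            raise ValueError("track has frame gaps")

    def __len__(self):
        return len(self.frames)


@dataclass
class MsdCurve:
    """Time-averaged MSD of one track (or an ensemble average)."""

    lags: np.ndarray    # lag times, s
    msd: np.ndarray     # µm²
    counts: np.ndarray  # displacements averaged per lag


@dataclass
class DiffusionEstimate:
    """Linear-fit result on an MSD curve."""

    D: float            # µm²/s; may be negative for noise-dominated tracks
    b: float            # intercept, µm²
    sigma_loc: float | None = None  # µm, when the radicand is nonnegative

    def recover_sigma(self, dt: float):
        """Invert the intercept relation for the static localization error."""
        radicand = (self.b + 4 * self.D * dt / 3) / 4
        self.sigma_loc = math.sqrt(radicand) if radicand >= 0 else None
        return self.sigma_loc


@dataclass
class DMixtureFit:
    """Gaussian decomposition of a per-track D histogram."""

    mode: str                     # "one" or "two"
    params: dict                  # fitted coefficients
    residual_norm: float
    bin_centers: np.ndarray
    density: np.ndarray


def tracks_from_dataframe(df: pd.DataFrame, pixel_size: float = PIXEL_SIZE_DEFAULT,
                          dt: float = DT_DEFAULT, min_length: int = 1):
    """Convert a tracks table (movie_id, track_id, frame, x_px, y_px) to Tracks."""
    out = []
    for (_, _), grp in df.groupby(["movie_id", "track_id"], sort=False):
        if len(grp) < min_length:
            continue
        grp = grp.sort_values("frame")
        out.append(Track(frames=grp["frame"].to_numpy(),
                         xy=grp[["x_px", "y_px"]].to_numpy() * pixel_size,
                         dt=dt))
    return out


# ---------------------------------------------------------------------------
# MSD
# ---------------------------------------------------------------------------

def time_averaged_msd(track: Track, max_k: int) -> MsdCurve:
    """Time-averaged MSD over overlapping windows for lags 1..max_k frames."""
    n = len(track)
    if n < max_k + 1:
        raise ValueError(f"track length {n} < max_k + 1 = {max_k + 1}")
    xy = track.xy
    msd = np.empty(max_k)
    counts = np.empty(max_k, dtype=int)
    for k in range(1, max_k + 1):
        d = xy[k:] - xy[:-k]
        msd[k - 1] = np.mean(np.sum(d * d, axis=1))
        counts[k - 1] = n - k
    return MsdCurve(lags=track.dt * np.arange(1, max_k + 1), msd=msd,
                    counts=counts)


def eata_msd(tracks, max_k: int) -> MsdCurve:
    """Ensemble-averaged time-averaged MSD: unweighted mean over tracks."""
    curves = [time_averaged_msd(t, max_k) for t in tracks]
    if not curves:
        raise ValueError("no tracks")
    msd = np.mean([c.msd for c in curves], axis=0)
    counts = np.sum([c.counts for c in curves], axis=0)
    return MsdCurve(lags=curves[0].lags, msd=msd, counts=counts)


def fit_track_D(msd: MsdCurve, dt: float, n_points: int = 3) -> DiffusionEstimate:
    """OLS of MSD against lag time over the first ``n_points`` lags.

    Slope/4 gives D; the intercept b is kept as fitted (it may be negative).
    The static localization error is recovered from
    ``b = -4*D*dt/3 + 4*sigma^2`` when the radicand is nonnegative.
    """
    if n_points < 2:
        raise ValueError("need at least 2 points for a line")
    if len(msd.lags) < n_points:
        raise ValueError(f"MSD has {len(msd.lags)} lags < n_points={n_points}")
    tau = msd.lags[:n_points]
    y = msd.msd[:n_points]
    slope, b = np.polyfit(tau, y, 1)
    est = DiffusionEstimate(D=slope / 4.0, b=b)
    est.recover_sigma(dt)
    return est


def ensemble_D(tracks, min_length: int = MIN_FIT_LENGTH, n_points: int = 3):
    """Mean +/- SEM of per-track D over tracks of at least ``min_length`` frames.

    Negative per-track D values are retained: truncating them would bias the
    ensemble mean upward, and the stationary-emitter control contextualizes
    the noise floor instead.

    Returns ``(mean, sem, per-track D array)``.
    """
    Ds = []
    for t in tracks:
        if len(t) < min_length:
            continue
        est = fit_track_D(time_averaged_msd(t, n_points), t.dt, n_points)
        Ds.append(est.D)
    Ds = np.asarray(Ds)
    if len(Ds) < 2:
        raise ValueError("need >=2 qualifying tracks")
    return float(Ds.mean()), float(Ds.std(ddof=1) / math.sqrt(len(Ds))), Ds


# ---------------------------------------------------------------------------
# D-histogram mixture fits
# ---------------------------------------------------------------------------

def _one_pop(D, c, mu, sig):
    return c / (sig * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((D - mu) / sig) ** 2)


def _two_pop(D, c, a, mu1, sig1, mu2, sig2):
    return c / np.sqrt(2 * np.pi) * (
        a / sig1 * np.exp(-0.5 * ((D - mu1) / sig1) ** 2)
        + (1 - a) / sig2 * np.exp(-0.5 * ((D - mu2) / sig2) ** 2))


def fit_D_histogram(Ds, mode: str = "one", fixed_a: float | None = None) -> DMixtureFit:
    """Least-squares Gaussian fit of the per-track D histogram.

    ``mode='one'`` fits a single scaled Gaussian; ``mode='two'`` a
    two-population form whose first-population fraction ``a`` may be fixed
    (e.g. to an independently measured membrane-bound fraction) or left
    free. The histogram is density-normalized with Freedman-Diaconis bins.
    """
    Ds = np.asarray(Ds, float)
    if len(Ds) < 100:
        raise ValueError("need >=100 D values for a histogram fit")
    iqr = np.subtract(*np.percentile(Ds, [75, 25]))
    width = 2 * iqr / len(Ds) ** (1 / 3)
    n_bins = max(10, int(np.ceil((Ds.max() - Ds.min()) / width))) if width > 0 else 10
    density, edges = np.histogram(Ds, bins=n_bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    mu0, sig0 = Ds.mean(), max(Ds.std(), 1e-6)
    try:
        if mode == "one":
            popt, _ = curve_fit(_one_pop, centers, density,
                                p0=[1.0, mu0, sig0], maxfev=20000)
            params = dict(zip(("c", "mu", "sigma"), popt))
            resid = density - _one_pop(centers, *popt)
        elif mode == "two":
            q25, q75 = np.percentile(Ds, [25, 75])
            if fixed_a is None:
                p0 = [1.0, 0.5, q25, sig0 / 2, q75, sig0 / 2]
                bounds = ([0, 0, -np.inf, 1e-9, -np.inf, 1e-9],
                          [np.inf, 1, np.inf, np.inf, np.inf, np.inf])
                popt, _ = curve_fit(_two_pop, centers, density, p0=p0,
                                    bounds=bounds, maxfev=20000)
            else:
                if not (0.0 <= fixed_a <= 1.0):
                    raise ValueError("fixed_a must be in [0, 1]")

                def f(D, c, mu1, sig1, mu2, sig2):
                    return _two_pop(D, c, fixed_a, mu1, sig1, mu2, sig2)

                if fixed_a == 1.0:
                    # second population carries no weight; pin it harmlessly
                    popt1, _ = curve_fit(_one_pop, centers, density,
                                         p0=[1.0, mu0, sig0], maxfev=20000)
                    popt = [popt1[0], fixed_a, popt1[1], popt1[2], mu0, sig0]
                    params = dict(zip(("c", "a", "mu1", "sigma1", "mu2",
                                       "sigma2"), popt))
                    resid = density - _two_pop(centers, *popt)
                    return DMixtureFit(mode=mode, params=params,
                                       residual_norm=float(np.linalg.norm(resid)),
                                       bin_centers=centers, density=density)
                # place the initial means at the quantile centers of the two
                # populations implied by the fixed fraction
                m1 = np.quantile(Ds, fixed_a / 2)
                m2 = np.quantile(Ds, (1 + fixed_a) / 2)
                p0 = [1.0, m1, sig0 / 2, m2, sig0 / 2]
                fb = ([0, -np.inf, 1e-9, -np.inf, 1e-9],
                      [np.inf, np.inf, np.inf, np.inf, np.inf])
                popt, _ = curve_fit(f, centers, density, p0=p0, bounds=fb,
                                    maxfev=20000)
                popt = [popt[0], fixed_a, *popt[1:]]
            params = dict(zip(("c", "a", "mu1", "sigma1", "mu2", "sigma2"), popt))
            resid = density - _two_pop(centers, *popt)
        else:
            raise ValueError("mode must be 'one' or 'two'")
    except RuntimeError as exc:
        raise RuntimeError(f"D-histogram fit did not converge: {exc}") from exc
    return DMixtureFit(mode=mode, params=params,
                       residual_norm=float(np.linalg.norm(resid)),
                       bin_centers=centers, density=density)


# ---------------------------------------------------------------------------
# linking radius
# ---------------------------------------------------------------------------

def adaptive_link_radius(D_5pix: float, dt: float = DT_DEFAULT,
                         pixel_size: float = PIXEL_SIZE_DEFAULT) -> int:
    """Maximum linking radius, in pixels, from a preliminary D estimate.

    ``ceil(2*sqrt(4*D*dt)/pixel_size)`` with a floor of 1 pixel: twice the
    RMS frame displacement expected at the preliminary diffusion coefficient
    ``D_5pix``, converted to pixels. At the default frame interval and pixel
    size the radius steps from 1 to 2 at D = 0.0737 µm²/s and from 2 to 3 at
    0.295 µm²/s.
    """
    if D_5pix < 0:
        raise ValueError("D_5pix must be nonnegative")
    radius = math.ceil(2 * math.sqrt(4 * D_5pix * dt) / pixel_size)
    return max(radius, 1)
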