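"""Synthetic single-molecule tracking data with known ground truth.

Generates the three inputs of the analysis pipeline — cell outlines, spot
tracks, and mRNA decay time courses — with the statistical structure the
downstream methods assume, so that every stage can be validated by parameter
recovery. Cells are straight, axis-aligned spherocylinders. A fraction
``m_true`` of molecules diffuses laterally on the cylindrical membrane
surface (coefficient ``D_mem``); the rest diffuse in the cytoplasmic volume
(``D_cyto``) with reflection at the membrane. Recorded positions include
motion blur (average over ``n_sub`` substeps per frame), isotropic Gaussian
localization error in the imaging plane, depth-dependent detection loss
through a soft focal cutoff, and single-step photobleaching giving
geometrically distributed track lengths.

Units: physical quantities in µm and seconds; emitted tables in pixels and
frame indices, matching the conventions of particle-tracking output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy.special import ndtr  # standard normal CDF, vectorized

from .geometry import CellGeometry
from .kinetics import DecayTimeCourse

MAX_TRACK_FRAMES = 200     # cap on simulated track length (p_bleach=0 guard)
DECAY_T_SWITCH = 255.0     # s; junction between the two decay regimes


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults describe the imaging setup (21.7 ms frames, 160 nm pixels) and
    an RNase-E-like experiment: mostly membrane-bound molecules diffusing at
    ~0.02 µm²/s, a ~5x faster cytoplasmic population, 20 nm localization
    error, and minute-scale mRNA decay.
    """

    n_cells: int = 200
    L_mean: float = 3.0        # cell length, µm
    L_sd: float = 0.5
    R_mean: float = 0.45       # cell half-width, µm
    R_sd: float = 0.03
    m_true: float = 0.93       # membrane fraction
    D_mem: float = 0.0184      # µm²/s
    D_cyto: float = 0.09       # µm²/s
    dt: float = 0.0217         # frame interval, s
    n_sub: int = 10            # motion-blur substeps per frame
    sigma_loc: float = 0.02    # localization error, µm
    f_depth: float = 0.35      # focal depth below cell midplane, µm
    sigma_z: float = 0.02      # axial detection softness, µm (= sigma_loc:
                               # the analysis model ties defocus softness to
                               # the localization error)
    p_bleach: float = 0.125    # per-frame bleach probability
    spots_per_cell: float = 500.0  # mean localizations per cell
    dilF_true: float = 1.15    # bright-field outline dilation: the detected
                               # cell boundary lies outside the membrane by
                               # this factor (label at r = R_outline/dilF)
    pixel_size: float = 0.160  # µm/pixel
    seed: int = 0
    k_d1_true: float = 0.02    # co-transcriptional decay rate, 1/s
    k_d2_true: float = 0.008   # post-transcriptional decay rate, 1/s
    cv_noise: float = 0.1      # multiplicative noise CV for decay curves

    def __post_init__(self):
        self.validate()

    def validate(self):
        if not (0.0 <= self.m_true <= 1.0):
            raise ConfigError("m_true must be in [0, 1]")
        if not self.L_mean > 2 * self.R_mean:
            raise ConfigError("L_mean must exceed 2*R_mean")
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        if self.n_cells < 1:
            raise ConfigError("n_cells must be >= 1")
        if self.n_sub < 1:
            raise ConfigError("n_sub must be >= 1")
        if not (0.0 <= self.p_bleach <= 1.0):
            raise ConfigError("p_bleach must be in [0, 1]")
        if self.dilF_true < 1.0:
            raise ConfigError("dilF_true must be >= 1")
        for name in ("L_mean", "L_sd", "R_mean", "R_sd", "D_mem", "D_cyto",
                     "sigma_loc", "sigma_z", "spots_per_cell", "pixel_size",
                     "k_d1_true", "k_d2_true", "cv_noise", "f_depth"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.pixel_size == 0:
            raise ConfigError("pixel_size must be positive")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class GroundTruth:
    """Per-molecule truth emitted alongside the tracks.

    ``molecules``: DataFrame with molecule_id, cell_id, label
    (membrane/cytoplasm), D_true (µm²/s). ``positions``: DataFrame with the
    motion-blurred true 3D position per frame (µm, cell-local frame: axial
    a in [0, L], transverse x, depth z) plus the detection flag and the
    track_id the frame was recorded under (-1 if undetected).
    """

    molecules: pd.DataFrame
    positions: pd.DataFrame


# ---------------------------------------------------------------------------
# cells
# ---------------------------------------------------------------------------

def _spherocylinder_outline(L: float, R: float, n_cap: int = 17,
                            n_side: int = 8) -> np.ndarray:
    """Local-frame outline of a spherocylinder spanning a in [0, L], |x|<=R.

    ``n_cap`` is odd so the pole tips are exact polygon vertices and the
    tip-to-tip centerline stays inside the outline.
    """
    th_r = np.linspace(-np.pi / 2, np.pi / 2, n_cap)         # right cap
    right = np.column_stack([(L - R) + R * np.cos(th_r), R * np.sin(th_r)])
    top = np.column_stack([np.linspace(L - R, R, n_side + 2)[1:-1],
                           np.full(n_side, R)])
    th_l = np.linspace(np.pi / 2, 3 * np.pi / 2, n_cap)       # left cap
    left = np.column_stack([R + R * np.cos(th_l), R * np.sin(th_l)])
    bottom = np.column_stack([np.linspace(R, L - R, n_side + 2)[1:-1],
                              np.full(n_side, -R)])
    return np.vstack([right, top, left, bottom])


def simulate_cells(config: SimConfig, rng: np.random.Generator | None = None
                   ) -> list[CellGeometry]:
    """Draw cell geometries and lay them out in a synthetic movie.

    Lengths and half-widths are truncated normals (rejected until L > 2R and
    R > 0). Cells are axis-aligned (long axis along image x), stacked along
    image y with clearance so outlines never overlap, and emitted in pixel
    units. All cells share movie_id 0.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_cells
    L = np.empty(n)
    R = np.empty(n)
    todo = np.ones(n, dtype=bool)
    for _ in range(1000):
        k = int(todo.sum())
        if k == 0:
            break
        L[todo] = rng.normal(config.L_mean, config.L_sd, size=k)
        R[todo] = rng.normal(config.R_mean, config.R_sd, size=k)
        todo = ~((L > 2 * R) & (R > 0))
    else:
        raise ConfigError("L_mean/R_mean: truncated-normal sampling did not converge")

    px = config.pixel_size
    pitch_px = (2 * R.max() + 1.0) / px   # 1 µm clearance between rows
    x0_px = 5.0
    cells = []
    for i in range(n):
        yc = (i + 1) * pitch_px
        outline = _spherocylinder_outline(L[i], R[i]) / px
        outline[:, 0] += x0_px
        outline[:, 1] += yc
        centerline = np.array([[x0_px, yc], [x0_px + L[i] / px, yc]])
        cells.append(CellGeometry(cell_id=i, movie_id=0, outline=outline,
                                  centerline=centerline,
                                  length_px=L[i] / px, width_px=2 * R[i] / px))
    return cells


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

def _cell_frames_px(cells):
    """Per-cell local-frame origin (pole tip) and axis row, px."""
    origins = np.array([c.centerline[0] for c in cells])
    return origins


def _reflect_interval(x, lo, hi):
    """Fold positions back into [lo, hi] (specular reflection)."""
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return y + lo


def simulate_tracks(cells: list[CellGeometry], config: SimConfig,
                    rng: np.random.Generator | None = None):
    """Simulate molecule motion, imaging, and detection for each cell.

    Each molecule is membrane-bound with probability ``m_true`` (lateral
    diffusion on the cylinder surface in the flattened (arc-length, axial)
    chart, reflecting at the cap junctions) or cytoplasmic (3D diffusion in
    the spherocylinder volume, reflecting at the membrane). Per frame the
    recorded position is the mean of ``n_sub`` substep positions plus
    Gaussian localization noise in the two imaged axes; the frame is
    detected with probability Phi((f_depth + z)/sigma_z) where z is the
    molecule's depth relative to the cell midplane (molecules near the far
    side of the focal plane are lost). Undetected frames split a molecule's
    record into separate tracks, since gap closing is disabled downstream.

    Returns ``(tracks DataFrame, GroundTruth)``; tracks have columns
    movie_id, track_id, frame, x_px, y_px.
    """
    if not cells:
        raise ValueError("cells must be non-empty")
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)

    px = config.pixel_size
    Ls = np.array([c.L * px for c in cells])   # µm, outline dimensions
    Rs = np.array([c.R * px for c in cells])
    origins = _cell_frames_px(cells)

    # molecules per cell: mean track length is 1/p_bleach, so this Poisson
    # rate gives on average spots_per_cell emitted localizations per cell
    rate = config.spots_per_cell * max(config.p_bleach, 1.0 / MAX_TRACK_FRAMES)
    n_mol_per_cell = rng.poisson(rate, size=len(cells))
    n_mol = int(n_mol_per_cell.sum())
    if n_mol == 0:
        raise ValueError("no molecules drawn; increase spots_per_cell")

    cell_idx = np.repeat(np.arange(len(cells)), n_mol_per_cell)
    Lm = Ls[cell_idx]
    Rm = Rs[cell_idx]
    # the bright-field outline is dilated relative to the membrane: the
    # physical cell is a spherocylinder of radius rm = R/dilF_true whose
    # cap centers coincide with the outline's pole centers
    rm = Rm / config.dilF_true
    ax_lo = Rm
    ax_hi = Lm - Rm
    is_mem = rng.random(n_mol) < config.m_true
    if config.p_bleach > 0:
        lifetime = np.minimum(rng.geometric(config.p_bleach, size=n_mol),
                              MAX_TRACK_FRAMES)
    else:
        lifetime = np.full(n_mol, MAX_TRACK_FRAMES)

    # --- initial positions (cell-local frame: a axial in [0,L], x, z) ---
    a = np.empty(n_mol)
    x = np.empty(n_mol)
    z = np.empty(n_mol)
    theta = np.zeros(n_mol)  # membrane angular coordinate
    mem = np.where(is_mem)[0]
    cyt = np.where(~is_mem)[0]
    # membrane: uniform on the cylindrical surface
    theta[mem] = rng.uniform(0, 2 * np.pi, size=len(mem))
    a[mem] = rng.uniform(ax_lo[mem], ax_hi[mem])
    # cytoplasm: uniform in the spherocylinder volume by rejection
    todo = cyt.copy()
    while len(todo):
        at = rng.uniform(ax_lo[todo] - rm[todo], ax_hi[todo] + rm[todo])
        xt = rng.uniform(-rm[todo], rm[todo])
        zt = rng.uniform(-rm[todo], rm[todo])
        s = np.clip(at, ax_lo[todo], ax_hi[todo])
        ok = (at - s) ** 2 + xt ** 2 + zt ** 2 <= rm[todo] ** 2
        a[todo[ok]] = at[ok]
        x[todo[ok]] = xt[ok]
        z[todo[ok]] = zt[ok]
        todo = todo[~ok]
    x[mem] = rm[mem] * np.cos(theta[mem])
    z[mem] = rm[mem] * np.sin(theta[mem])

    dt_sub = config.dt / config.n_sub
    sd_mem = math.sqrt(2 * config.D_mem * dt_sub)
    sd_cyt = math.sqrt(2 * config.D_cyto * dt_sub)

    n_frames = int(lifetime.max())
    rec_a = np.zeros((n_frames, n_mol))
    rec_x = np.zeros((n_frames, n_mol))
    rec_z = np.zeros((n_frames, n_mol))

    for f in range(n_frames):
        active = lifetime > f
        mem = np.where(active & is_mem)[0]
        cyt = np.where(active & ~is_mem)[0]
        acc_a = np.zeros(n_mol)
        acc_x = np.zeros(n_mol)
        acc_z = np.zeros(n_mol)
        for _ in range(config.n_sub):
            if len(mem):
                # flattened (arc-length, axial) chart on the cylinder
                theta[mem] += rng.normal(0, sd_mem, size=len(mem)) / rm[mem]
                a[mem] = _reflect_interval(
                    a[mem] + rng.normal(0, sd_mem, size=len(mem)),
                    ax_lo[mem], ax_hi[mem])
                x[mem] = rm[mem] * np.cos(theta[mem])
                z[mem] = rm[mem] * np.sin(theta[mem])
            if len(cyt):
                a[cyt] += rng.normal(0, sd_cyt, size=len(cyt))
                x[cyt] += rng.normal(0, sd_cyt, size=len(cyt))
                z[cyt] += rng.normal(0, sd_cyt, size=len(cyt))
                # reflect at the spherocylinder boundary (mirror across the
                # nearest membrane point; exact for small substeps)
                s = np.clip(a[cyt], ax_lo[cyt], ax_hi[cyt])
                da = a[cyt] - s
                d = np.sqrt(da ** 2 + x[cyt] ** 2 + z[cyt] ** 2)
                out = d > rm[cyt]
                if np.any(out):
                    scale = (2 * rm[cyt][out] - d[out]) / d[out]
                    a[cyt[out]] = s[out] + da[out] * scale
                    x[cyt[out]] *= scale
                    z[cyt[out]] *= scale
            acc_a += a
            acc_x += x
            acc_z += z
        rec_a[f] = acc_a / config.n_sub
        rec_x[f] = acc_x / config.n_sub
        rec_z[f] = acc_z / config.n_sub

    # --- imaging: detection, localization noise, pixel coordinates ---
    alive = np.arange(n_frames)[:, None] < lifetime[None, :]
    if config.sigma_z > 0:
        p_det = ndtr((config.f_depth + rec_z) / config.sigma_z)
    else:
        p_det = (rec_z > -config.f_depth).astype(float)
    detected = alive & (rng.random((n_frames, n_mol)) < p_det)

    obs_a = rec_a + rng.normal(0, config.sigma_loc, size=rec_a.shape)
    obs_x = rec_x + rng.normal(0, config.sigma_loc, size=rec_x.shape)

    # split each molecule's detected frames into gapless tracks
    det = detected.T  # (n_mol, n_frames)
    starts = det & ~np.concatenate(
        [np.zeros((n_mol, 1), bool), det[:, :-1]], axis=1)
    track_of = np.where(det, np.cumsum(starts.flatten()).reshape(det.shape), 0)
    # track ids 1..n_tracks over the flattened order; remap to 0-based
    mol_grid, frame_grid = np.meshgrid(np.arange(n_mol), np.arange(n_frames),
                                       indexing="ij")
    mask = det.flatten()
    mol_f = mol_grid.flatten()[mask]
    frame_f = frame_grid.flatten()[mask]
    tid_f = track_of.flatten()[mask] - 1

    ax = obs_a.T.flatten()[mask]
    xx = obs_x.T.flatten()[mask]
    x_px = origins[cell_idx[mol_f], 0] + ax / px
    y_px = origins[cell_idx[mol_f], 1] + xx / px

    cell_ids = np.array([c.cell_id for c in cells])
    tracks = pd.DataFrame({
        "movie_id": np.array([cells[i].movie_id for i in cell_idx[mol_f]]),
        "track_id": tid_f,
        "frame": frame_f,
        "x_px": x_px,
        "y_px": y_px,
    })

    molecules = pd.DataFrame({
        "molecule_id": np.arange(n_mol),
        "cell_id": cell_ids[cell_idx],
        "label": np.where(is_mem, "membrane", "cytoplasm"),
        "D_true": np.where(is_mem, config.D_mem, config.D_cyto),
        "lifetime_frames": lifetime,
    })
    alive_f = alive.T.flatten()
    positions = pd.DataFrame({
        "molecule_id": mol_grid.flatten()[alive_f],
        "frame": frame_grid.flatten()[alive_f],
        "a_um": rec_a.T.flatten()[alive_f],
        "x_um": rec_x.T.flatten()[alive_f],
        "z_um": rec_z.T.flatten()[alive_f],
        "detected": det.flatten()[alive_f],
        "track_id": np.where(det.flatten(), track_of.flatten() - 1, -1)[alive_f],
    })

    return tracks, GroundTruth(molecules=molecules, positions=positions)


def simulate_free_tracks(n_tracks: int, n_frames: int, D: float,
                         config: SimConfig | None = None,
                         rng: np.random.Generator | None = None):
    """Unconfined planar Brownian tracks with motion blur and noise.

    Reference tracks for validating the MSD estimator itself: free 2D
    diffusion at coefficient ``D`` (µm²/s), recorded as the mean of
    ``config.n_sub`` substep positions per frame plus isotropic Gaussian
    localization error. No cell geometry, detection loss, or bleaching —
    all tracks have exactly ``n_frames`` frames. (Tracks confined to a cell
    or to the curved membrane surface have a geometrically rescaled
    apparent D; this helper isolates the estimator from those effects.)

    Returns a list of (n_frames, 2) position arrays in µm.
    """
    if config is None:
        config = SimConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    dt_sub = config.dt / config.n_sub
    sd = math.sqrt(2 * D * dt_sub)
    steps = rng.normal(0, sd, size=(n_tracks, n_frames * config.n_sub, 2))
    pos = np.cumsum(steps, axis=1)
    blurred = pos.reshape(n_tracks, n_frames, config.n_sub, 2).mean(axis=2)
    blurred += rng.normal(0, config.sigma_loc, size=blurred.shape)
    return [blurred[i] for i in range(n_tracks)]


# ---------------------------------------------------------------------------
# decay
# ---------------------------------------------------------------------------

def simulate_decay(config: SimConfig, sample_times,
                   n_replicates: int = 3,
                   rng: np.random.Generator | None = None,
                   t_switch: float = DECAY_T_SWITCH) -> list[DecayTimeCourse]:
    """Two-regime exponential mRNA decay with multiplicative noise.

    Abundance follows exp(-k_d1 * t) up to ``t_switch`` and continues
    continuously with rate k_d2 afterwards. Noise is multiplicative
    lognormal with coefficient of variation ``cv_noise`` (qPCR-like,
    mean-one), independent across samples and replicates.
    """
    config.validate()
    times = np.asarray(sample_times, float)
    if times.size == 0:
        raise ValueError("sample_times must be non-empty")
    if np.any(np.diff(times) <= 0):
        raise ValueError("sample_times must be strictly increasing")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)

    k1, k2 = config.k_d1_true, config.k_d2_true
    clean = np.where(times <= t_switch,
                     np.exp(-k1 * times),
                     np.exp(-k1 * t_switch - k2 * (times - t_switch)))
    out = []
    for rep in range(n_replicates):
        if config.cv_noise > 0:
            s = math.sqrt(math.log(1 + config.cv_noise ** 2))
            noise = np.exp(rng.normal(-s * s / 2, s, size=times.size))
        else:
            noise = np.ones_like(times)
        out.append(DecayTimeCourse(replicate_id=rep, times=times.copy(),
                                   abundance=clean * noise))
    return out
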