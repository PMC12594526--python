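"""Cell-coordinate normalization of single-molecule localizations.

Rod-shaped bacteria are near-cylindrical, so a localization is best described
in the cell's own frame: an axial coordinate along the centerline (``yNorm``,
0 at one pole, 1 at the other) and a signed transverse coordinate
perpendicular to it (``xNorm``, -1 and +1 on the two membrane edges,
normalized by the cell half-width ``R``). This module assigns spots to cells,
corrects a rigid drift between the bright-field cell outlines and the
fluorescence data, performs the normalization, restricts spots to the
cylindrical mid-region of the cell (``R < y < L - R``), and builds the
binned distribution of ``|xNorm|`` whose shape encodes the fraction of
membrane-bound molecules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from shapely.strtree import STRtree

logger = logging.getLogger(__name__)

XNORM_BIN_WIDTH = 0.04  # default histogram bin width in normalized units
FRAMES_PER_TRACK = 4    # localizations per track entering the histogram
DRIFT_THRESHOLD_PX = 0.5


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent cell geometry."""


class AmbiguousCellsError(GeometryError):
    """Raised when cell outlines overlap, making spot assignment ambiguous."""

    def __init__(self, pairs):
        self.pairs = list(pairs)
        super().__init__(f"overlapping cell outlines: {self.pairs}")


@dataclass
class CellGeometry:
    """A single cell's outline and axis frame, in pixel units.

    Parameters
    ----------
    cell_id : int
        Unique id within the movie.
    movie_id : int
        Movie the cell belongs to.
    outline : (N, 2) array
        Simple polygon tracing the cell boundary (vertices px; not repeated).
    centerline : (M, 2) array
        Ordered polyline from pole to pole; its arc length equals ``length_px``
        for straight cells.
    length_px : float
        Cell length L along the centerline, px.
    width_px : float
        Mean cell width (2R), px.
    """

    cell_id: int
    movie_id: int
    outline: np.ndarray
    centerline: np.ndarray
    length_px: float
    width_px: float

    _polygon: Polygon = field(init=False, repr=False, default=None)

    def __post_init__(self):
        self.outline = np.asarray(self.outline, dtype=float)
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.outline.ndim != 2 or self.outline.shape[0] < 3:
            raise GeometryError(f"cell {self.cell_id}: outline needs >=3 vertices")
        if self.centerline.ndim != 2 or self.centerline.shape[0] < 2:
            raise GeometryError(f"cell {self.cell_id}: centerline needs >=2 points")
        if not (self.length_px > self.width_px > 0):
            raise GeometryError(
                f"cell {self.cell_id}: need L > 2R > 0, got "
                f"L={self.length_px}, 2R={self.width_px}"
            )
        poly = Polygon(self.outline)
        if not poly.is_valid:
            raise GeometryError(f"cell {self.cell_id}: outline polygon is not simple")
        self._polygon = poly
        # pole-to-pole endpoints may sit exactly on the boundary
        tol = poly.buffer(1e-6)
        for end in (self.centerline[0], self.centerline[-1]):
            if not tol.covers(Point(end)):
                raise GeometryError(
                    f"cell {self.cell_id}: centerline endpoint {end} outside outline"
                )
        seg = np.diff(self.centerline, axis=0)
        self._seg_len = np.hypot(seg[:, 0], seg[:, 1])
        if np.any(self._seg_len == 0):
            raise GeometryError(f"cell {self.cell_id}: zero-length centerline segment")
        self._seg = seg
        self._cum_s = np.concatenate([[0.0], np.cumsum(self._seg_len)])

    @property
    def R(self) -> float:
        """Half mean width, px."""
        return self.width_px / 2.0

    @property
    def L(self) -> float:
        """Cell length, px."""
        return self.length_px

    @property
    def polygon(self) -> Polygon:
        return self._polygon

    def project(self, xy: np.ndarray):
        """Project points onto the centerline.

        Returns ``(s, d_signed)``: arc-length position along the centerline and
        the signed perpendicular distance, positive to the left of the local
        tangent (sign of the cross product tangent x offset).
        """
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        p0 = self.centerline[:-1]  # (S,2)
        seg = self._seg
        lens2 = (self._seg_len ** 2)
        # per point, per segment projection parameter clamped to [0,1]
        diff = xy[:, None, :] - p0[None, :, :]          # (N,S,2)
        t = np.einsum("nsk,sk->ns", diff, seg) / lens2  # (N,S)
        t = np.clip(t, 0.0, 1.0)
        proj = p0[None, :, :] + t[:, :, None] * seg[None, :, :]
        off = xy[:, None, :] - proj
        dist2 = np.einsum("nsk,nsk->ns", off, off)
        best = np.argmin(dist2, axis=1)                 # (N,)
        idx = np.arange(xy.shape[0])
        tb = t[idx, best]
        s = self._cum_s[best] + tb * self._seg_len[best]
        tangent = seg[best] / self._seg_len[best, None]
        offb = off[idx, best]
        cross = tangent[:, 0] * offb[:, 1] - tangent[:, 1] * offb[:, 0]
        d = np.sqrt(dist2[idx, best])
        return s, np.where(cross >= 0, d, -d)


@dataclass
class XnormHistogram:
    """Binned distribution of (absolute) normalized transverse positions."""

    edges: np.ndarray        # bin edges, length n_bins + 1
    prob: np.ndarray         # per-bin probability, sums to 1
    sem: np.ndarray          # bootstrap SEM per bin
    n_spots: int
    absolute: bool

    def __post_init__(self):
        self.edges = np.asarray(self.edges, float)
        self.prob = np.asarray(self.prob, float)
        self.sem = np.asarray(self.sem, float)
        if abs(self.prob.sum() - 1.0) > 1e-9:
            raise ValueError("histogram probabilities must sum to 1")
        if np.any(self.sem < 0):
            raise ValueError("SEM must be nonnegative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])


# ---------------------------------------------------------------------------
# spot -> cell assignment
# ---------------------------------------------------------------------------

def _check_no_overlap(cells):
    polys = [c.polygon for c in cells]
    tree = STRtree(polys)
    bad = []
    for i, p in enumerate(polys):
        for j in tree.query(p):
            j = int(j)
            if j <= i:
                continue
            inter = p.intersection(polys[j])
            if inter.area > 1e-9:
                bad.append((cells[i].cell_id, cells[j].cell_id))
    if bad:
        raise AmbiguousCellsError(bad)


def assign_spots(spots: pd.DataFrame, cells: list[CellGeometry]) -> pd.DataFrame:
    """Assign each spot to the cell whose outline contains it.

    Spots inside no cell are dropped. Each track is kept only if a strict
    majority of its in-cell spots falls in a single cell; tracks straddling
    cells without a strict majority are dropped, and spots of a kept track
    that lie outside its assigned cell are dropped with it.

    Parameters
    ----------
    spots : DataFrame with columns movie_id, track_id, frame, x_px, y_px.
    cells : cell geometries of the same movie(s).

    Returns
    -------
    DataFrame: the surviving spots with an added ``cell_id`` column.
    """
    _check_no_overlap(cells)
    out_frames = []
    by_movie = {}
    for c in cells:
        by_movie.setdefault(c.movie_id, []).append(c)
    for movie_id, grp in spots.groupby("movie_id"):
        mcells = by_movie.get(movie_id, [])
        if not mcells:
            continue
        polys = [c.polygon for c in mcells]
        tree = STRtree(polys)
        pts = [Point(x, y) for x, y in zip(grp["x_px"], grp["y_px"])]
        cell_idx = np.full(len(pts), -1, dtype=int)
        for k, pt in enumerate(pts):
            for j in tree.query(pt, predicate="covered_by"):
                cell_idx[k] = int(j)
                break
        g = grp.copy()
        g["_ci"] = cell_idx
        g = g[g["_ci"] >= 0]
        keep = []
        for tid, tgrp in g.groupby("track_id"):
            counts = tgrp["_ci"].value_counts()
            if counts.iloc[0] * 2 > counts.sum():
                ci = counts.index[0]
                keep.append(tgrp[tgrp["_ci"] == ci])
        if keep:
            g = pd.concat(keep)
            g["cell_id"] = [mcells[i].cell_id for i in g["_ci"]]
            out_frames.append(g.drop(columns="_ci"))
    if not out_frames:
        return spots.iloc[0:0].assign(cell_id=pd.Series(dtype=int))
    return pd.concat(out_frames, ignore_index=True)


# ---------------------------------------------------------------------------
# drift correction
# ---------------------------------------------------------------------------

def estimate_drift(assigned: pd.DataFrame, cells: list[CellGeometry],
                   min_spots: int = 10,
                   threshold_px: float = DRIFT_THRESHOLD_PX) -> dict:
    """Per-movie rigid shift between cell outlines and fluorescence data.

    For every cell with at least ``min_spots`` assigned spots, the offset
    between the outline center and the centroid of its spots is computed; the
    movie's shift is the mean of these offsets. Shifts smaller in magnitude
    than ``threshold_px`` are reported as zero (no correction applied).

    Returns a dict ``movie_id -> np.ndarray([dx, dy])`` giving the shift to
    ADD to spot coordinates.
    """
    lookup = {(c.movie_id, c.cell_id): c for c in cells}
    shifts = {}
    for movie_id, grp in assigned.groupby("movie_id"):
        offsets = []
        for cid, cgrp in grp.groupby("cell_id"):
            if len(cgrp) < min_spots:
                continue
            cell = lookup[(movie_id, cid)]
            center = np.asarray(cell.polygon.centroid.coords[0])
            centroid = np.array([cgrp["x_px"].mean(), cgrp["y_px"].mean()])
            offsets.append(center - centroid)
        if not offsets:
            logger.warning("movie %s: no cell with >=%d spots; drift not corrected",
                           movie_id, min_spots)
            shifts[movie_id] = np.zeros(2)
            continue
        shift = np.mean(offsets, axis=0)
        if np.hypot(*shift) <= threshold_px:
            shift = np.zeros(2)
        shifts[movie_id] = shift
    return shifts


def apply_drift(spots: pd.DataFrame, shifts: dict) -> pd.DataFrame:
    """Add the per-movie shift to spot coordinates."""
    out = spots.copy()
    for movie_id, shift in shifts.items():
        mask = out["movie_id"] == movie_id
        out.loc[mask, "x_px"] += shift[0]
        out.loc[mask, "y_px"] += shift[1]
    return out


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_spots(assigned: pd.DataFrame, cells: list[CellGeometry]):
    """Convert assigned spots to normalized cell coordinates.

    ``yNorm`` is the arc-length position of the spot's projection on the
    centerline divided by L; ``xNorm`` is the signed perpendicular distance
    divided by R, the sign taken from the cross product of the local
    centerline tangent with the spot offset. Spots with ``|xNorm| > 1`` or
    ``yNorm`` outside [0, 1] (localization noise can push spots beyond the
    nominal boundary) are rejected, not clipped: clipping would pile mass
    into the outermost bin and bias the membrane fraction upward.

    Returns
    -------
    (DataFrame, dict)
        Normalized spots (columns cell_id, track_id, frame, xNorm, yNorm,
        y_px_axial) and a QC dict with counts of rejected spots.
    """
    lookup = {(c.movie_id, c.cell_id): c for c in cells}
    rows = []
    qc = {"n_in": len(assigned), "n_rejected_xnorm": 0, "n_rejected_ynorm": 0}
    for (movie_id, cid), grp in assigned.groupby(["movie_id", "cell_id"]):
        cell = lookup[(movie_id, cid)]
        s, d = cell.project(grp[["x_px", "y_px"]].to_numpy())
        ynorm = s / cell.L
        xnorm = d / cell.R
        ok_x = np.abs(xnorm) <= 1.0
        ok_y = (ynorm >= 0.0) & (ynorm <= 1.0)
        qc["n_rejected_xnorm"] += int(np.sum(~ok_x))
        qc["n_rejected_ynorm"] += int(np.sum(ok_x & ~ok_y))
        ok = ok_x & ok_y
        sub = grp.loc[ok, ["movie_id", "cell_id", "track_id", "frame"]].copy()
        sub["xNorm"] = xnorm[ok]
        sub["yNorm"] = ynorm[ok]
        sub["y_px_axial"] = s[ok]
        rows.append(sub)
    if not rows:
        cols = ["movie_id", "cell_id", "track_id", "frame", "xNorm", "yNorm",
                "y_px_axial"]
        return pd.DataFrame(columns=cols), qc
    return pd.concat(rows, ignore_index=True), qc


def normalize_spot(cell: CellGeometry, x_px: float, y_px: float):
    """Normalize a single spot; returns ``(xNorm, yNorm)`` or None if rejected."""
    s, d = cell.project([[x_px, y_px]])
    xnorm, ynorm = d[0] / cell.R, s[0] / cell.L
    if abs(xnorm) > 1.0 or not (0.0 <= ynorm <= 1.0):
        return None
    return xnorm, ynorm


def cylinder_filter(normspots: pd.DataFrame, cells: list[CellGeometry]) -> pd.DataFrame:
    """Flag spots in the cylindrical part of the cell, ``R < y < L - R``.

    The hemispherical endcaps distort the transverse-position distribution, so
    only the cylindrical mid-region enters the histogram. Adds a boolean
    ``in_cylinder`` column (open interval: spots exactly at y = R or L - R
    are flagged endcap).
    """
    lookup = {(c.movie_id, c.cell_id): c for c in cells}
    out = normspots.copy()
    flags = np.zeros(len(out), dtype=bool)
    for (movie_id, cid), grp in out.groupby(["movie_id", "cell_id"]):
        cell = lookup[(movie_id, cid)]
        y = grp["y_px_axial"].to_numpy()
        flags[out.index.get_indexer(grp.index)] = (y > cell.R) & (y < cell.L - cell.R)
    out["in_cylinder"] = flags
    return out


# ---------------------------------------------------------------------------
# histogram
# ---------------------------------------------------------------------------

def build_xnorm_histogram(normspots: pd.DataFrame,
                          bin_width: float = XNORM_BIN_WIDTH,
                          frames_per_track: int = FRAMES_PER_TRACK,
                          n_boot: int = 100,
                          seed: int = 0,
                          absolute: bool = True) -> XnormHistogram:
    """Build the xNorm histogram from the first localizations of each track.

    Only localizations from the first ``frames_per_track`` frames of each
    track enter, so every track contributes (up to) the same number of
    points and temporal correlation within long tracks does not dominate
    the histogram. Tracks shorter than ``frames_per_track`` localizations
    are discarded, mirroring the minimum-track-length guarantee of the
    tracking step (without it, short fragments from detection flicker near
    the focal cutoff are over-represented). When the input carries
    ``track_len`` and ``track_first_frame`` columns (added by
    :func:`normalize_movie` from the raw track table) the selection uses
    the track's true span, so a first-frame spot rejected at the cell
    boundary is simply lost rather than replaced by a later one — dropping
    it keeps the per-localization boundary truncation that the projection
    model assumes. The bootstrap resamples TRACKS (not individual spots) so
    the SEM respects the within-track dependence of those points.
    ``absolute=True`` folds x to |x| onto [0, 1].
    """
    df = normspots
    if "in_cylinder" in df.columns:
        df = df[df["in_cylinder"]]
    if len(df) == 0:
        raise ValueError("no spots left after filtering")
    if "track_len" in df.columns and "track_first_frame" in df.columns:
        df = df[df["track_len"] >= frames_per_track]
        df = df[df["frame"] < df["track_first_frame"] + frames_per_track]
    else:
        grouped = df.sort_values("frame").groupby(
            ["movie_id", "cell_id", "track_id"], sort=False)
        df = grouped.filter(lambda g: len(g) >= frames_per_track)
        df = df.sort_values("frame").groupby(
            ["movie_id", "cell_id", "track_id"], sort=False).head(frames_per_track)
    if len(df) == 0:
        raise ValueError(f"no tracks with >= {frames_per_track} localizations")

    x = df["xNorm"].to_numpy()
    if absolute:
        x = np.abs(x)
        lo, hi = 0.0, 1.0
    else:
        lo, hi = -1.0, 1.0
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)

    def _hist(vals):
        counts, _ = np.histogram(vals, bins=edges)
        return counts / counts.sum()

    prob = _hist(x)

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        keys = df.groupby(["movie_id", "cell_id", "track_id"], sort=False).ngroup().to_numpy()
        n_tracks = keys.max() + 1
        order = np.argsort(keys, kind="stable")
        xs = x[order]
        bounds = np.searchsorted(keys[order], np.arange(n_tracks + 1))
        boots = np.empty((n_boot, n_bins))
        for b in range(n_boot):
            pick = rng.integers(0, n_tracks, size=n_tracks)
            vals = np.concatenate([xs[bounds[i]:bounds[i + 1]] for i in pick])
            boots[b] = _hist(vals)
        sem = boots.std(axis=0, ddof=1)
    else:
        sem = np.zeros(n_bins)

    return XnormHistogram(edges=edges, prob=prob, sem=sem,
                          n_spots=len(x), absolute=absolute)


def normalize_movie(spots: pd.DataFrame, cells: list[CellGeometry],
                    drift_min_spots: int = 10,
                    drift_threshold_px: float = DRIFT_THRESHOLD_PX):
    """Full spot-normalization pipeline for one or more movies.

    Assign spots to cells, estimate and apply the drift correction,
    re-assign, normalize, and flag the cylindrical region.

    Returns ``(normalized DataFrame with in_cylinder flag, qc dict)``.
    """
    assigned = assign_spots(spots, cells)
    shifts = estimate_drift(assigned, cells, min_spots=drift_min_spots,
                            threshold_px=drift_threshold_px)
    if any(np.any(s != 0) for s in shifts.values()):
        assigned = assign_spots(apply_drift(spots, shifts), cells)
    norm, qc = normalize_spots(assigned, cells)
    # per-track span from the raw table, so downstream selection can apply
    # the tracking step's minimum length and first-frames rule faithfully
    stats = spots.groupby(["movie_id", "track_id"])["frame"].agg(
        track_len="size", track_first_frame="min").reset_index()
    norm = norm.merge(stats, on=["movie_id", "track_id"], how="left")
    qc["drift_shifts"] = {k: tuple(v) for k, v in shifts.items()}
    return cylinder_filter(norm, cells), qc
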