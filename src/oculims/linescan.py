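"""Arc-length line scan along the tissue outer perimeter.

The analysis traces the outer contour of the tissue section, parameterizes it
by arc length with the corneal apex at position 0, places circular ROIs
(default diameter 200 μm) at fixed arc spacing (default 400 μm) on the
superior and inferior branches, averages the TIC-normalized target-ion
intensity over the laser spots inside each ROI, and compares superior vs
inferior ROIs equidistant from the apex with a two-sided Mann-Whitney U test.

The Mann-Whitney implementation is self-contained: an exact p-value by full
enumeration of labelings of the pooled sample (used when n1+n2 <= 16, which
covers the 2-11 spots per ROI of perimeter line scans) and a tie- and
continuity-corrected normal approximation otherwise.  Ties are handled with
midranks in both paths.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import norm, rankdata

from .images import IonImage
from .imzml import Coord, MSIDataset

__all__ = [
    "BoundaryPath",
    "ROI",
    "ROISeries",
    "MannWhitneyResult",
    "PositionComparison",
    "LineScanResult",
    "trace_boundary",
    "set_origin",
    "place_rois",
    "assign_spots",
    "mann_whitney_u",
    "compare_symmetric_positions",
]

logger = logging.getLogger(__name__)

Branch = Literal["superior", "inferior", "apex"]

EXACT_MAX_POOLED = 16  # exact enumeration up to C(16, 8) = 12870 labelings


# ---------------------------------------------------------------------------
# Boundary tracing and arc-length parameterization
# ---------------------------------------------------------------------------

@dataclass
class BoundaryPath:
    """Closed (or open) contour in physical μm, arc-length parameterized.

    ``points`` holds the polyline vertices without a duplicated closing
    vertex; for closed paths the segment from the last back to the first
    point is implied.  After :func:`set_origin`, vertex 0 is the corneal
    apex (arc position 0) and ``superior_sign`` says whether increasing
    vertex index (+1) or decreasing (-1) walks the superior branch.
    """

    points: np.ndarray  # (n, 2) x, y in μm
    pitch_um: float
    closed: bool = True
    origin_set: bool = False
    superior_sign: int = 1
    origin_arc_um: float = 0.0  # forward arc of the origin (nonzero only for open paths)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if self.points.shape[0] < 2:
            raise ValueError("a path needs at least two points")

    @property
    def cumulative_length(self) -> np.ndarray:
        """Arc length at each vertex, starting at 0 (closing segment excluded)."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def total_length(self) -> float:
        length = float(self.cumulative_length[-1])
        if self.closed:
            length += float(np.linalg.norm(self.points[0] - self.points[-1]))
        return length

    def point_at_forward_arc(self, s: float) -> np.ndarray:
        """Interpolate the point at forward arc length ``s`` from vertex 0."""
        total = self.total_length
        if self.closed:
            s = s % total
            cum = np.concatenate([self.cumulative_length, [total]])
            pts = np.vstack([self.points, self.points[:1]])
        else:
            if s < 0 or s > total:
                raise ValueError(f"arc {s} outside open path [0, {total}]")
            cum = self.cumulative_length
            pts = self.points
        x = np.interp(s, cum, pts[:, 0])
        y = np.interp(s, cum, pts[:, 1])
        return np.array([x, y])

    def point_at_branch_arc(self, arc_um: float, branch: str) -> np.ndarray:
        """Point at unsigned arc distance from the origin along a branch."""
        if not self.origin_set:
            raise ValueError("origin not set; call set_origin first")
        if branch == "apex":
            return self.point_at_forward_arc(self.origin_arc_um)
        sign = self.superior_sign if branch == "superior" else -self.superior_sign
        return self.point_at_forward_arc(self.origin_arc_um + sign * arc_um)


def _moving_average_closed(points: np.ndarray, window: int) -> np.ndarray:
    """Circular moving average of contour vertices (suppresses pixel staircase)."""
    if window <= 1:
        return points
    if window % 2 == 0:
        window += 1
    half = window // 2
    padded = np.vstack([points[-half:], points, points[:half]])
    kernel = np.ones(window) / window
    out = np.empty_like(points)
    for k in (0, 1):
        out[:, k] = np.convolve(padded[:, k], kernel, mode="valid")
    return out


def trace_boundary(
    mask: np.ndarray,
    pitch_um: float,
    simplify_tol_px: float = 1.0,
    smooth_window: int = 0,
) -> BoundaryPath:
    """Trace the outer contour of the largest connected tissue component.

    The marching-squares contour of a binary mask zigzags along the pixel
    staircase, inflating arc length; Douglas-Peucker simplification at
    ``simplify_tol_px`` (pixels) straightens the staircase while preserving
    genuine corners, keeping the traced perimeter within a few percent of
    the true outline for both smooth and polygonal shapes.  An optional
    circular moving average (``smooth_window`` vertices) can be applied
    afterwards for display purposes.

    Parameters
    ----------
    mask
        Boolean (ny, nx) tissue mask aligned to the pixel grid; entry
        ``[y-1, x-1]`` corresponds to pixel ``(x, y)``.
    pitch_um
        Pixel pitch in μm; physical positions are ``(index - 1) * pitch``.

    Raises
    ------
    ValueError
        Empty mask, or several equally large components (the caller must
        then select one).
    """
    from skimage import measure

    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("tissue mask is empty")
    labels = measure.label(mask, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    top = int(sizes.max())
    winners = np.flatnonzero(sizes == top)
    if len(winners) > 1:
        raise ValueError(
            f"{len(winners)} connected components share the largest size "
            f"({top} px); select one component and retry"
        )
    component = labels == winners[0]
    # pad so components touching the array edge still yield closed contours
    padded = np.pad(component, 1).astype(float)
    contours = measure.find_contours(padded, 0.5)
    contour = max(contours, key=lambda c: len(c))  # outer contour is longest
    rc = contour - 1.0  # undo padding
    if not np.allclose(rc[0], rc[-1]):
        rc = np.vstack([rc, rc[:1]])
    if simplify_tol_px > 0:
        rc = measure.approximate_polygon(rc, tolerance=simplify_tol_px)
    if np.allclose(rc[0], rc[-1]):
        rc = rc[:-1]
    points = np.column_stack([rc[:, 1], rc[:, 0]]) * pitch_um  # (x, y) μm
    points = _moving_average_closed(points, smooth_window)
    return BoundaryPath(points=points, pitch_um=pitch_um, closed=True)


def _project_onto_path(path: BoundaryPath, target: np.ndarray):
    """Nearest point on the polyline to ``target``: (distance, segment idx, point)."""
    pts = path.points
    if path.closed:
        a = pts
        b = np.vstack([pts[1:], pts[:1]])
    else:
        a = pts[:-1]
        b = pts[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom == 0] = 1.0
    t = np.clip(np.einsum("ij,ij->i", target - a, ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    dist = np.linalg.norm(proj - target, axis=1)
    k = int(np.argmin(dist))
    return float(dist[k]), k, proj[k], float(t[k])


def set_origin(
    path: BoundaryPath,
    apex_xy: Sequence[float],
    superior_hint_xy: Sequence[float],
) -> BoundaryPath:
    """Re-anchor the path at the corneal apex and label the superior branch.

    The apex is projected onto the contour (error if farther than twice the
    pixel pitch) and inserted as vertex 0; the traversal direction whose
    half-perimeter contains the point nearest ``superior_hint_xy`` is
    labeled superior.
    """
    apex = np.asarray(apex_xy, dtype=np.float64)
    hint = np.asarray(superior_hint_xy, dtype=np.float64)
    dist, seg, proj, t = _project_onto_path(path, apex)
    if dist > 2.0 * path.pitch_um:
        raise ValueError(
            f"apex {tuple(apex)} is {dist:.1f} μm from the contour "
            f"(> 2 x pitch = {2 * path.pitch_um:.1f} μm)"
        )
    pts = path.points
    n = pts.shape[0]
    if not path.closed:
        raise ValueError("set_origin requires a closed contour")
    # insert the projected apex as the new first vertex
    order = np.roll(np.arange(n), -(seg + 1))
    rolled = pts[order]
    if t >= 1.0 - 1e-12:  # projection coincides with the next vertex
        new_pts = rolled
    else:
        new_pts = np.vstack([proj, rolled]) if not np.allclose(proj, rolled[0]) else rolled
    out = BoundaryPath(
        points=new_pts, pitch_um=path.pitch_um, closed=True, origin_set=True
    )
    # decide which direction is superior
    _, hseg, hproj, ht = _project_onto_path(out, hint)
    cum = out.cumulative_length
    total = out.total_length
    seg_start = cum[hseg]
    seg_end = cum[hseg + 1] if hseg + 1 < len(cum) else total
    hint_arc = seg_start + ht * (seg_end - seg_start)
    out.superior_sign = 1 if hint_arc <= total / 2.0 else -1
    return out


# ---------------------------------------------------------------------------
# ROI placement and aggregation
# ---------------------------------------------------------------------------

@dataclass
class ROI:
    """Circular ROI on the perimeter: center, branch, arc distance from apex."""

    center_xy: Tuple[float, float]
    diameter_um: float
    branch: str  # "superior" | "inferior" | "apex"
    arc_um: float  # unsigned arc distance from the apex
    spots: List[Coord] = field(default_factory=list)
    values: Optional[np.ndarray] = None

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def mean_intensity(self) -> float:
        if self.values is None or len(self.values) == 0:
            return math.nan
        return float(np.mean(self.values))


@dataclass
class ROISeries:
    rois: List[ROI]
    diameter_um: float
    spacing_um: float

    def __len__(self) -> int:
        return len(self.rois)

    def branch(self, name: str) -> List[ROI]:
        return [r for r in self.rois if r.branch == name]


def place_rois(
    path: BoundaryPath,
    diameter_um: float = 200.0,
    spacing_um: float = 400.0,
    max_arc_um: Optional[float] = None,
) -> ROISeries:
    """Place ROI centers at arc positions 0, ±spacing, ±2·spacing, ... from the apex.

    One shared ROI sits at the apex (branch ``"apex"``); the others are
    labeled superior or inferior.  With spacing > diameter, same-branch ROI
    disks do not overlap.
    """
    if spacing_um <= 0:
        raise ValueError("ROI spacing must be positive")
    if diameter_um <= 0:
        raise ValueError("ROI diameter must be positive")
    if diameter_um > spacing_um:
        logger.warning(
            "ROI diameter %.0f μm exceeds spacing %.0f μm: disks will overlap",
            diameter_um,
            spacing_um,
        )
    if not path.origin_set:
        raise ValueError("origin not set; call set_origin first")
    total = path.total_length
    if max_arc_um is None:
        max_arc_um = total / 2.0 - spacing_um if path.closed else total
    if path.closed:
        # past the half-perimeter the branches would wrap onto each other
        max_arc_um = min(max_arc_um, total / 2.0)
    apex_center = path.point_at_branch_arc(0.0, "apex")
    rois: List[ROI] = [
        ROI(
            center_xy=(float(apex_center[0]), float(apex_center[1])),
            diameter_um=diameter_um,
            branch="apex",
            arc_um=0.0,
        )
    ]
    for branch in ("superior", "inferior"):
        arc = spacing_um
        while arc <= max_arc_um + 1e-9:
            try:
                center = path.point_at_branch_arc(arc, branch)
            except ValueError:  # open path: this branch has run off the end
                break
            rois.append(
                ROI(
                    center_xy=(float(center[0]), float(center[1])),
                    diameter_um=diameter_um,
                    branch=branch,
                    arc_um=float(arc),
                )
            )
            arc += spacing_um
    return ROISeries(rois=rois, diameter_um=diameter_um, spacing_um=spacing_um)


def assign_spots(
    series: ROISeries, dataset: MSIDataset, ion: IonImage
) -> ROISeries:
    """Assign laser spots (pixels) to ROIs and compute per-ROI mean intensity.

    A pixel belongs to an ROI iff its physical center lies inside the ROI
    disk.  ROIs with no spots (e.g. disks over unscanned regions) are
    dropped with a warning.
    """
    if not ion.normalized:
        logger.warning("assigning spots from a non-normalized ion image")
    coords = [c for c in dataset.spectra if c in ion.values]
    if not coords:
        return ROISeries(rois=[], diameter_um=series.diameter_um,
                         spacing_um=series.spacing_um)
    positions = np.array([dataset.physical_xy(c) for c in coords])
    tree = cKDTree(positions)
    radius = series.diameter_um / 2.0
    kept: List[ROI] = []
    dropped = 0
    for roi in series.rois:
        idx = tree.query_ball_point(np.asarray(roi.center_xy), r=radius)
        if not idx:
            dropped += 1
            continue
        spots = [coords[i] for i in sorted(idx)]
        values = np.array([ion.values[c] for c in spots], dtype=np.float64)
        kept.append(replace(roi, spots=spots, values=values))
    if dropped:
        logger.warning("dropped %d ROI(s) containing no laser spots", dropped)
    return ROISeries(rois=kept, diameter_um=series.diameter_um,
                     spacing_um=series.spacing_um)


# ---------------------------------------------------------------------------
# Mann-Whitney U test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # U statistic of the first sample
    p_two_sided: float
    method: str  # "exact" | "normal_approx"


@lru_cache(maxsize=128)
def _combination_indices(n: int, k: int) -> np.ndarray:
    """All C(n, k) index subsets as a (C, k) integer array (cached)."""
    return np.array(list(itertools.combinations(range(n), k)), dtype=np.intp)


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "auto",
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    ``U`` counts pairs with ``x_i > y_j`` plus half the tied pairs
    (midranks).  The exact p-value enumerates all ``C(n1+n2, n1)`` labelings
    of the observed pooled values (default whenever ``n1 + n2 <= 16``);
    otherwise a normal approximation with tie and continuity corrections is
    used.  ``method`` is one of ``"exact"``, ``"normal_approx"``, ``"auto"``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    if method not in ("exact", "normal_approx", "auto"):
        raise ValueError(f"unknown method {method!r}")
    use_exact = method == "exact" or (method == "auto" and n <= EXACT_MAX_POOLED)

    if use_exact:
        combos = _combination_indices(n, n1)
        u_all = ranks[combos].sum(axis=1) - n1 * (n1 + 1) / 2.0
        eps = 1e-9
        p_le = float(np.mean(u_all <= u + eps))
        p_ge = float(np.mean(u_all >= u - eps))
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return MannWhitneyResult(u=u, p_two_sided=p, method="exact")

    mean_u = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return MannWhitneyResult(u=u, p_two_sided=1.0, method="normal_approx")
    diff = u - mean_u
    cc = 0.5 * np.sign(diff)  # continuity correction toward the mean
    z = (diff - cc) / math.sqrt(var_u)
    p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return MannWhitneyResult(u=u, p_two_sided=p, method="normal_approx")


# ---------------------------------------------------------------------------
# Superior vs inferior comparison at equidistant arc positions
# ---------------------------------------------------------------------------

@dataclass
class PositionComparison:
    arc_um: float
    superior_mean: float
    inferior_mean: float
    n_superior: int
    n_inferior: int
    u: float = math.nan
    p_two_sided: float = math.nan
    holm_p: float = math.nan
    tier: str = "none"  # "none" | "0.05" | "0.01"
    direction: str = ""  # "superior" | "inferior" | ""
    tested: bool = False


@dataclass
class LineScanResult:
    positions: List[PositionComparison]
    series: ROISeries

    def to_frame(self) -> pd.DataFrame:
        """One row per retained ROI, with the per-position test columns attached."""
        by_arc: Dict[float, PositionComparison] = {
            round(p.arc_um, 3): p for p in self.positions
        }
        rows = []
        for roi in sorted(self.series.rois, key=lambda r: (r.arc_um, r.branch)):
            cmp = by_arc.get(round(roi.arc_um, 3))
            rows.append(
                {
                    "arc_position_um": roi.arc_um,
                    "branch": roi.branch,
                    "n_spots": roi.n_spots,
                    "mean_norm_intensity": roi.mean_intensity,
                    "U": cmp.u if cmp and cmp.tested else math.nan,
                    "p_two_sided": cmp.p_two_sided if cmp and cmp.tested else math.nan,
                    "holm_p": cmp.holm_p if cmp and cmp.tested else math.nan,
                    "tier": cmp.tier if cmp else "none",
                    "direction": cmp.direction if cmp else "",
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str) -> None:
        frame = self.to_frame()
        frame.to_csv(path, sep="\t", index=False, float_format="%.8g")


def compare_symmetric_positions(
    series: ROISeries,
    alpha_levels: Tuple[float, float] = (0.05, 0.01),
    method: str = "auto",
) -> LineScanResult:
    """Mann-Whitney comparison of superior vs inferior ROIs equidistant from
    the apex.

    For every arc position present on both branches, the member-spot
    intensities of the two ROIs are compared two-sided; the direction is the
    branch with the larger mean, and the significance tier uses the given
    alpha levels (no multiple-testing correction, matching per-position
    reporting; a Holm-adjusted column is emitted alongside).  Positions
    present on only one branch are reported without a test.
    """
    alpha_lo, alpha_hi = max(alpha_levels), min(alpha_levels)
    sup = {round(r.arc_um, 3): r for r in series.branch("superior")}
    inf = {round(r.arc_um, 3): r for r in series.branch("inferior")}
    comparisons: List[PositionComparison] = []
    for arc in sorted(set(sup) | set(inf)):
        s, i = sup.get(arc), inf.get(arc)
        if s is not None and i is not None:
            res = mann_whitney_u(s.values, i.values, method=method)
            s_mean, i_mean = s.mean_intensity, i.mean_intensity
            if res.p_two_sided < alpha_hi:
                tier = f"{alpha_hi:g}"
            elif res.p_two_sided < alpha_lo:
                tier = f"{alpha_lo:g}"
            else:
                tier = "none"
            if s_mean > i_mean:
                direction = "superior"
            elif i_mean > s_mean:
                direction = "inferior"
            else:
                direction = ""
            comparisons.append(
                PositionComparison(
                    arc_um=float(arc),
                    superior_mean=s_mean,
                    inferior_mean=i_mean,
                    n_superior=s.n_spots,
                    n_inferior=i.n_spots,
                    u=res.u,
                    p_two_sided=res.p_two_sided,
                    tier=tier if direction else "none",
                    direction=direction,
                    tested=True,
                )
            )
        else:
            comparisons.append(
                PositionComparison(
                    arc_um=float(arc),
                    superior_mean=s.mean_intensity if s else math.nan,
                    inferior_mean=i.mean_intensity if i else math.nan,
                    n_superior=s.n_spots if s else 0,
                    n_inferior=i.n_spots if i else 0,
                    tested=False,
                )
            )
    # Holm adjustment across the tested positions (reported, not used for tiers)
    tested = [c for c in comparisons if c.tested]
    if tested:
        order = np.argsort([c.p_two_sided for c in tested])
        m = len(tested)
        running = 0.0
        for rank, idx in enumerate(order):
            adj = (m - rank) * tested[idx].p_two_sided
            running = max(running, min(1.0, adj))
            tested[idx].holm_p = running
    return LineScanResult(positions=comparisons, series=series)
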