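"""Synthetic AFM-image rendering and strand-trace vectorization.

The DNA-origami frame provides the geometric reference for every
single-molecule measurement: a rectangular frame hosts three parallel
internal duplexes (Control, NPF and Reaction rows) suspended between anchor
points on opposite edges, and an asymmetric polarity marker at one corner
fixes the orientation, hence strand identity and sequence direction.

``render_frame`` draws a frame plus strand polylines as Gaussian-profile
height ridges with additive pixel noise -- a controllable stand-in for a
flattened HS-AFM topograph. ``vectorize`` inverts it: smooth, threshold,
locate the frame-border ridge crests, detect the polarity marker, extract
per-column ridge centroids inside the frame window and track them into three
labelled strand polylines. ``intersection_position`` measures where the NPF
strand contacts a target strand, as an arclength along the target from the
end furthest from the polarity marker.

The vectorization design (threshold / crest location / centroid tracking)
is a standard re-creation of ridge tracing for AFM topographs; it is
validated by round-trip recovery of planted ground truth on synthetic
renders, and targets such synthetic fixtures and simple real crops only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import tifffile
import yaml
from scipy.ndimage import gaussian_filter
from scipy.optimize import linear_sum_assignment
from scipy.signal import find_peaks
from scipy.spatial.distance import cdist

__all__ = [
    "FrameGeometry",
    "AFMImage",
    "StrandTrace",
    "VectorizationResult",
    "GeometryError",
    "DetectionError",
    "render_frame",
    "vectorize",
    "intersection_position",
    "pixel_size_nm",
    "write_afm_image",
    "read_afm_image",
]

STRAND_ROWS = ("Control", "NPF", "Reaction")

CORNERS = ("NW", "NE", "SW", "SE")


class GeometryError(ValueError):
    """Raised when traces or geometry do not fit the image field."""


class DetectionError(RuntimeError):
    """Raised when the frame or polarity marker cannot be identified."""


def pixel_size_nm(field_nm: float = 1000.0, n_pixels: int = 256) -> float:
    """Pixel size of a square scan: field edge / pixel count.

    The typical acquisition (1 um field at 256 x 256) gives ~3.9 nm, usually
    quoted as ~4 nm.
    """
    if field_nm <= 0 or n_pixels < 1:
        raise ValueError("field and pixel count must be positive")
    return field_nm / n_pixels


@dataclass(frozen=True)
class FrameGeometry:
    """Reference geometry of the origami frame in image coordinates.

    Image coordinates: x rightward, y downward, nm; the frame-outline
    centreline rectangle has its top-left corner at ``origin``.

    ``border_nm`` is the inset from the outline centreline to the anchor
    lines on which the internal strands terminate; the usable span between
    anchors (the reaction window) is ``width_nm - 2 * border_nm``, ~40 nm by
    design (43.52 nm here, the B-form contour of a 128-bp duplex, so that a
    fully stretched internal strand spans anchor to anchor).

    The three strand rows lie at ``border_nm``, ``height_nm / 2`` and
    ``height_nm - border_nm`` below the top outline; row identity (Control,
    NPF, Reaction) is assigned by increasing distance from the polarity
    marker's edge.
    """

    width_nm: float = 43.52 + 16.0
    height_nm: float = 60.0
    border_nm: float = 8.0
    origin: Tuple[float, float] = (10.0, 10.0)
    polarity_marker_corner: str = "NW"

    def __post_init__(self) -> None:
        if self.polarity_marker_corner not in CORNERS:
            raise GeometryError(
                f"polarity_marker_corner must be one of {CORNERS}"
            )
        if self.reaction_window_nm <= 0:
            raise GeometryError("reaction window must be positive")

    @property
    def reaction_window_nm(self) -> float:
        """Span available to the internal strands, anchor to anchor (nm)."""
        return self.width_nm - 2.0 * self.border_nm

    @property
    def outline_corners(self) -> Dict[str, Tuple[float, float]]:
        x0, y0 = self.origin
        return {
            "NW": (x0, y0),
            "NE": (x0 + self.width_nm, y0),
            "SW": (x0, y0 + self.height_nm),
            "SE": (x0 + self.width_nm, y0 + self.height_nm),
        }

    @property
    def marker_xy(self) -> Tuple[float, float]:
        return self.outline_corners[self.polarity_marker_corner]

    def row_ys(self) -> Dict[str, float]:
        """Map strand label -> row y (nm). Rows are ordered Control, NPF,
        Reaction by increasing distance from the marker's horizontal edge."""
        y0 = self.origin[1]
        ys = [y0 + self.border_nm, y0 + self.height_nm / 2.0,
              y0 + self.height_nm - self.border_nm]
        marker_y = self.marker_xy[1]
        ordered = sorted(ys, key=lambda y: abs(y - marker_y))
        return dict(zip(STRAND_ROWS, ordered))

    def anchor_pair(self, label: str) -> Tuple[Tuple[float, float], Tuple[float, float]]:
        """Anchor points (left, right) of a strand row, on opposite frame edges."""
        y = self.row_ys()[label]
        x0 = self.origin[0]
        return ((x0 + self.border_nm, y),
                (x0 + self.width_nm - self.border_nm, y))

    def strand_trace(self, label: str) -> "StrandTrace":
        """Straight ground-truth trace of a strand suspended between anchors."""
        a, b = self.anchor_pair(label)
        return StrandTrace(points=np.array([a, b]), strand_label=label)

    def npf_trace_with_contact(
        self,
        position_nm: float,
        target_label: str = "Reaction",
        separation_nm: float = 4.5,
        shoulder_nm: float = 12.0,
    ) -> "StrandTrace":
        """NPF ground-truth trace dipping towards ``target_label`` so that the
        point of closest approach sits ``position_nm`` along the target from
        the end furthest from the polarity marker, with ``separation_nm``
        between the ridge centrelines at closest approach."""
        if not 0.0 <= position_nm <= self.reaction_window_nm:
            raise GeometryError(
                f"contact position {position_nm} nm outside the "
                f"{self.reaction_window_nm:.2f} nm reaction window"
            )
        (ax, ay), (bx, by) = self.anchor_pair("NPF")
        t_left, t_right = self.anchor_pair(target_label)
        mx = self.marker_xy[0]
        # origin end of the target = anchor furthest from the marker
        if abs(t_left[0] - mx) >= abs(t_right[0] - mx):
            x_contact = t_left[0] + position_nm
        else:
            x_contact = t_right[0] - position_nm
        y_target = self.row_ys()[target_label]
        y_npf = ay
        y_apex = y_target - separation_nm if y_target > y_npf else y_target + separation_nm
        pts = [(ax, ay)]
        if x_contact - shoulder_nm > ax:
            pts.append((x_contact - shoulder_nm, y_npf))
        pts.append((x_contact, y_apex))
        if x_contact + shoulder_nm < bx:
            pts.append((x_contact + shoulder_nm, y_npf))
        pts.append((bx, by))
        return StrandTrace(points=np.array(pts), strand_label="NPF")

    def mirrored_vertically(self) -> "FrameGeometry":
        """Same frame with the marker moved to the vertically opposite corner."""
        flip = {"NW": "SW", "SW": "NW", "NE": "SE", "SE": "NE"}
        return FrameGeometry(
            width_nm=self.width_nm,
            height_nm=self.height_nm,
            border_nm=self.border_nm,
            origin=self.origin,
            polarity_marker_corner=flip[self.polarity_marker_corner],
        )


@dataclass(frozen=True)
class AFMImage:
    """One AFM topograph: height grid in nm plus acquisition metadata."""

    height: np.ndarray
    pixel_size: float
    frame_time: float = 1.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.height.ndim != 2:
            raise ValueError("height grid must be 2-D")

    @property
    def field_nm(self) -> Tuple[float, float]:
        ny, nx = self.height.shape
        return (nx * self.pixel_size, ny * self.pixel_size)


@dataclass(frozen=True)
class StrandTrace:
    """Ordered polyline of (x, y) points in nm tracing one strand."""

    points: np.ndarray
    strand_label: str = "frame"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError("trace needs at least 2 (x, y) points")
        object.__setattr__(self, "points", pts)

    @property
    def arclength(self) -> float:
        """Total polyline length; always >= the end-to-end distance."""
        seg = np.diff(self.points, axis=0)
        return float(np.sqrt((seg ** 2).sum(axis=1)).sum())

    @property
    def end_to_end(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))

    def resample(self, step: float = 0.25) -> np.ndarray:
        """Points at (approximately) uniform arclength spacing ``step`` nm."""
        pts = self.points
        seg = np.diff(pts, axis=0)
        seglen = np.sqrt((seg ** 2).sum(axis=1))
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        total = cum[-1]
        if total == 0:
            return pts[:1]
        n = max(2, int(np.ceil(total / step)) + 1)
        s = np.linspace(0.0, total, n)
        x = np.interp(s, cum, pts[:, 0])
        y = np.interp(s, cum, pts[:, 1])
        return np.column_stack([x, y])

    def arclength_to(self, idx: int, resampled: np.ndarray) -> float:
        seg = np.diff(resampled[: idx + 1], axis=0)
        return float(np.sqrt((seg ** 2).sum(axis=1)).sum()) if idx > 0 else 0.0


# ---------------------------------------------------------------------------
# Rendering

RIDGE_HEIGHT_NM = 2.0       # apparent strand height over background
RIDGE_SIGMA_NM = 1.2        # Gaussian ridge half-width
FRAME_HEIGHT_NM = 2.5       # frame outline is slightly taller than strands
MARKER_HEIGHT_NM = 4.0      # polarity marker protrusion
MARKER_SIGMA_NM = 2.5


def _paint_segment(height: np.ndarray, xs: np.ndarray, ys: np.ndarray,
                   p0: np.ndarray, p1: np.ndarray, amp: float, sigma: float) -> None:
    """Max-compose a Gaussian-profile ridge along segment p0-p1 into height."""
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0:
        dist2 = (xs - p0[0]) ** 2 + (ys - p0[1]) ** 2
    else:
        t = ((xs - p0[0]) * d[0] + (ys - p0[1]) * d[1]) / L2
        t = np.clip(t, 0.0, 1.0)
        cx = p0[0] + t * d[0]
        cy = p0[1] + t * d[1]
        dist2 = (xs - cx) ** 2 + (ys - cy) ** 2
    np.maximum(height, amp * np.exp(-dist2 / (2.0 * sigma ** 2)), out=height)


def render_frame(
    geometry: FrameGeometry,
    traces: Sequence[StrandTrace],
    pixel_size: float = 1.0,
    noise_sd: float = 0.1,
    rng_seed: int = 0,
    frame_time: float = 1.0,
    ridge_height: float = RIDGE_HEIGHT_NM,
    ridge_sigma: float = RIDGE_SIGMA_NM,
) -> AFMImage:
    """Render an AFM-like topograph of the frame plus internal strands.

    Strands are Gaussian-profile ridges (height ``ridge_height`` nm, width
    ``ridge_sigma`` nm) max-composed over a flat background; the frame
    outline is drawn slightly taller and the polarity marker as a protruding
    blob at its corner. I.i.d. Gaussian pixel noise of ``noise_sd`` nm is
    added. Deterministic for a given ``rng_seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    x0, y0 = geometry.origin
    fw = geometry.width_nm + 2 * x0
    fh = geometry.height_nm + 2 * y0
    nx = int(np.ceil(fw / pixel_size))
    ny = int(np.ceil(fh / pixel_size))
    for tr in traces:
        if (tr.points[:, 0].min() < 0 or tr.points[:, 1].min() < 0
                or tr.points[:, 0].max() > fw or tr.points[:, 1].max() > fh):
            raise GeometryError(
                f"trace {tr.strand_label!r} extends outside the "
                f"{fw:.0f} x {fh:.0f} nm field"
            )
    # pixel-centre coordinates in nm
    xs, ys = np.meshgrid(
        (np.arange(nx) + 0.5) * pixel_size,
        (np.arange(ny) + 0.5) * pixel_size,
    )
    height = np.zeros((ny, nx), dtype=np.float64)
    corners = geometry.outline_corners
    outline = [corners["NW"], corners["NE"], corners["SE"], corners["SW"],
               corners["NW"]]
    for a, b in zip(outline[:-1], outline[1:]):
        _paint_segment(height, xs, ys, np.asarray(a), np.asarray(b),
                       FRAME_HEIGHT_NM, ridge_sigma)
    mx, my = geometry.marker_xy
    blob = MARKER_HEIGHT_NM * np.exp(
        -((xs - mx) ** 2 + (ys - my) ** 2) / (2.0 * MARKER_SIGMA_NM ** 2)
    )
    np.maximum(height, blob, out=height)
    for tr in traces:
        pts = tr.points
        for a, b in zip(pts[:-1], pts[1:]):
            _paint_segment(height, xs, ys, a, b, ridge_height, ridge_sigma)
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        height = height + rng.normal(0.0, noise_sd, size=height.shape)
    return AFMImage(height=height.astype(np.float32), pixel_size=pixel_size,
                    frame_time=frame_time)


# ---------------------------------------------------------------------------
# Vectorization


@dataclass(frozen=True)
class VectorizationResult:
    """Traces recovered from one image, with the detected frame reference."""

    traces: List[StrandTrace]
    marker_corner: str
    marker_xy: Tuple[float, float]
    outline_bbox: Tuple[float, float, float, float]  # x0, y0, x1, y1 (crest)

    def trace(self, label: str) -> StrandTrace:
        for tr in self.traces:
            if tr.strand_label == label:
                return tr
        raise KeyError(f"no trace labelled {label!r}")


def _crest_position(profile: np.ndarray, lo: int, hi: int) -> float:
    """Centroid-refined maximum of a 1-D profile restricted to [lo, hi)."""
    sub = profile[lo:hi]
    k = int(np.argmax(sub)) + lo
    a = max(lo, k - 2)
    b = min(hi, k + 3)
    w = profile[a:b].clip(min=0)
    if w.sum() == 0:
        return float(k)
    return float(np.average(np.arange(a, b), weights=w))


def vectorize(
    image: AFMImage,
    geometry: FrameGeometry,
    threshold_nm: float = 1.0,
    smooth_sigma_px: float = 1.0,
) -> VectorizationResult:
    """Vectorize one frame image into labelled internal strand traces.

    Steps: Gaussian-smooth; threshold at ``threshold_nm`` above background;
    locate the frame-border ridge crests from marginal height profiles;
    identify the polarity-marker corner as the tallest of the four outline
    corners; per interior column, extract ridge-run centroids and track them
    into three polylines by nearest-neighbour assignment; label rows
    Control / NPF / Reaction by increasing distance from the marker edge;
    extend traces to the anchor lines. All outputs in nm.
    """
    px = image.pixel_size
    h = gaussian_filter(image.height.astype(np.float64), smooth_sigma_px)
    mask = h > threshold_nm
    if not mask.any():
        raise DetectionError("no frame found: nothing above the height threshold")
    rows_any = np.where(mask.any(axis=1))[0]
    cols_any = np.where(mask.any(axis=0))[0]
    r0, r1 = rows_any[0], rows_any[-1] + 1
    c0, c1 = cols_any[0], cols_any[-1] + 1
    if (r1 - r0) * px < 3 * geometry.border_nm or (c1 - c0) * px < 3 * geometry.border_nm:
        raise DetectionError("no frame found: detected structure too small")
    hm = np.where(mask, h, 0.0)
    col_profile = hm.sum(axis=0)
    row_profile = hm.sum(axis=1)
    cmid = (c0 + c1) // 2
    rmid = (r0 + r1) // 2
    left = _crest_position(col_profile, c0, cmid)
    right = _crest_position(col_profile, cmid, c1)
    top = _crest_position(row_profile, r0, rmid)
    bottom = _crest_position(row_profile, rmid, r1)
    # crest coordinates in nm (pixel centres)
    x_left, x_right = (left + 0.5) * px, (right + 0.5) * px
    y_top, y_bottom = (top + 0.5) * px, (bottom + 0.5) * px
    corners_px = {
        "NW": (left, top), "NE": (right, top),
        "SW": (left, bottom), "SE": (right, bottom),
    }
    radius = max(2, int(round(5.0 / px)))
    corner_height = {}
    for name, (cx, cy) in corners_px.items():
        ci, ri = int(round(cx)), int(round(cy))
        a0, a1 = max(0, ri - radius), ri + radius + 1
        b0, b1 = max(0, ci - radius), ci + radius + 1
        corner_height[name] = float(h[a0:a1, b0:b1].max())
    ranked = sorted(corner_height, key=corner_height.get, reverse=True)
    if corner_height[ranked[0]] < 1.15 * corner_height[ranked[1]]:
        raise DetectionError(
            "polarity marker ambiguous: corner heights "
            + ", ".join(f"{k}={v:.2f}" for k, v in corner_height.items())
        )
    marker_corner = ranked[0]
    marker_xy = ((corners_px[marker_corner][0] + 0.5) * px,
                 (corners_px[marker_corner][1] + 0.5) * px)

    # interior region: clear of the border ridge
    margin_nm = 0.6 * geometry.border_nm
    ci0 = int(np.ceil((x_left + margin_nm) / px - 0.5))
    ci1 = int(np.floor((x_right - margin_nm) / px - 0.5))
    ri0 = int(np.ceil((y_top + margin_nm) / px - 0.5))
    ri1 = int(np.floor((y_bottom - margin_nm) / px - 0.5))
    if ci1 <= ci0 or ri1 <= ri0:
        raise DetectionError("frame interior is empty after border exclusion")

    # expected row ys relative to the detected outline
    inner_h = y_bottom - y_top
    expected_ys = np.array([
        y_top + geometry.border_nm,
        y_top + inner_h / 2.0,
        y_bottom - geometry.border_nm,
    ])
    track_pts: List[List[Tuple[float, float]]] = [[], [], []]
    prev_y = expected_ys.copy()
    for col in range(ci0, ci1 + 1):
        prof = h[ri0:ri1 + 1, col]
        peaks, _ = find_peaks(prof, height=threshold_nm, prominence=0.2)
        cands = []
        for k in peaks:
            # sub-pixel refinement: height-weighted centroid in a +/- 2 px
            # window around the peak (lower-variance than a 3-point parabola)
            a0, a1 = max(0, k - 2), min(prof.size, k + 3)
            w = prof[a0:a1].clip(min=0.0)
            ycent = (float(np.average(np.arange(a0, a1), weights=w)) + ri0 + 0.5) * px
            cands.append((ycent, float(prof[k])))
        if not cands:
            continue
        # keep the 3 tallest peaks, then assign to tracks
        cands.sort(key=lambda c: -c[1])
        cands = cands[:3]
        ys_cand = np.array([c[0] for c in cands])
        cost = np.abs(prev_y[:, None] - ys_cand[None, :])
        ti, cj = linear_sum_assignment(cost)
        xnm = (col + 0.5) * px
        for t, c in zip(ti, cj):
            track_pts[t].append((xnm, ys_cand[c]))
            prev_y[t] = ys_cand[c]
    if any(len(tp) < 2 for tp in track_pts):
        raise DetectionError("could not trace three internal strands")

    # label rows by distance from the marker edge and extend to anchor lines
    anchor_left = x_left + geometry.border_nm
    anchor_right = x_right - geometry.border_nm
    traces = []
    marker_y = marker_xy[1]
    order = np.argsort([abs(np.mean([p[1] for p in tp]) - marker_y)
                        for tp in track_pts])
    for label, t in zip(STRAND_ROWS, order):
        pts = np.array(track_pts[t])
        if pts.shape[0] >= 5:
            # light smoothing of the traced y: suppresses per-column centroid
            # jitter, which would otherwise inflate the polyline arclength
            ys = np.pad(pts[:, 1], 2, mode="reflect")
            kernel = np.ones(5) / 5.0
            pts = pts.copy()
            pts[:, 1] = np.convolve(ys, kernel, mode="valid")
        # clip to the anchor span, then extend the ends onto the anchor lines
        inside = (pts[:, 0] >= anchor_left) & (pts[:, 0] <= anchor_right)
        if inside.sum() >= 2:
            pts = pts[inside]
        first, last = pts[0], pts[-1]
        ext = list(pts)
        if first[0] > anchor_left:
            ext = [np.array([anchor_left, first[1]])] + ext
        if last[0] < anchor_right:
            ext = ext + [np.array([anchor_right, last[1]])]
        traces.append(StrandTrace(points=np.array(ext), strand_label=label))
    return VectorizationResult(
        traces=traces,
        marker_corner=marker_corner,
        marker_xy=marker_xy,
        outline_bbox=(x_left, y_top, x_right, y_bottom),
    )


# ---------------------------------------------------------------------------
# Intersection measurement

#: Default NPF-target contact threshold: two pixels at the typical 4 nm
#: pixel size -- below the strand-row spacing, above trace jitter.
CONTACT_THRESHOLD_NM = 8.0


def intersection_position(
    npf_trace: StrandTrace,
    target_trace: StrandTrace,
    geometry: FrameGeometry,
    marker_xy: Optional[Tuple[float, float]] = None,
    contact_threshold_nm: float = CONTACT_THRESHOLD_NM,
    step_nm: float = 0.25,
) -> Optional[float]:
    """Position (nm) along the target strand at which the NPF contacts it.

    Both polylines are resampled at ``step_nm``; the pair of points with
    minimal separation defines the contact. The returned value is the
    arclength along the target from the end furthest from the polarity
    marker to the contact point. Returns None ("no contact") when the
    minimal separation exceeds ``contact_threshold_nm``.
    """
    if npf_trace.points.shape[0] < 2 or target_trace.points.shape[0] < 2:
        raise ValueError("degenerate trace: need at least 2 points")
    if marker_xy is None:
        marker_xy = geometry.marker_xy
    a = npf_trace.resample(step_nm)
    b = target_trace.resample(step_nm)
    d = cdist(a, b)
    dmin = float(d.min())
    if dmin > contact_threshold_nm:
        return None
    # the separation profile can be nearly flat around the contact, so use
    # the centre of the near-minimal region rather than a single argmin
    col_min = d.min(axis=0)
    near = np.where(col_min <= dmin + 0.25)[0]
    j = int(round(float(np.median(near))))
    m = np.asarray(marker_xy)
    d_first = np.linalg.norm(b[0] - m)
    d_last = np.linalg.norm(b[-1] - m)
    seg = np.sqrt((np.diff(b, axis=0) ** 2).sum(axis=1))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if d_first >= d_last:
        return float(cum[j])
    return float(cum[-1] - cum[j])


def traces_to_tsv(result: VectorizationResult, path: str | Path) -> None:
    """Export vectorized traces as a TSV of polyline points (nm)."""
    with open(path, "w") as fh:
        fh.write(f"# marker_corner: {result.marker_corner}\n")
        fh.write("strand_label\tpoint_index\tx_nm\ty_nm\n")
        for tr in result.traces:
            for i, (x, y) in enumerate(tr.points):
                fh.write(f"{tr.strand_label}\t{i}\t{x:.3f}\t{y:.3f}\n")


# ---------------------------------------------------------------------------
# TIFF I/O (32-bit float heights in nm + YAML sidecar metadata)


def write_afm_image(image: AFMImage, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(str(path), image.height.astype(np.float32))
    meta = {"pixel_size_nm": float(image.pixel_size),
            "frame_time_s": float(image.frame_time)}
    with open(path.with_suffix(path.suffix + ".meta.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh)


def read_afm_image(path: str | Path) -> AFMImage:
    path = Path(path)
    height = tifffile.imread(str(path))
    with open(path.with_suffix(path.suffix + ".meta.yaml")) as fh:
        meta = yaml.safe_load(fh)
    return AFMImage(height=np.asarray(height, dtype=np.float32),
                    pixel_size=float(meta["pixel_size_nm"]),
                    frame_time=float(meta["frame_time_s"]))
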