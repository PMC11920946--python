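"""Gaze-contingent tessellation of the visual field.

The visual field is divided into a central disc plus five eccentricity
rings, each ring split into equal angular sectors (default 8), giving 41
independently weighted regions.  The map is retinotopic: for every movie
frame it is re-centred on the momentary gaze position before regional
luminance is computed, so regions index positions relative to the fovea,
not the screen.

Coordinates are in degrees of visual angle with the origin at the movie
centre, +x rightward and +y upward; a single pixels-per-degree scalar maps
to pixels (a flat display is assumed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RegionMap",
    "EventMatrix",
    "SaliencySummary",
    "build_region_map",
    "recenter",
    "extract_events",
    "summarize_saliency",
]

#: id of the off-map background class in label images
BACKGROUND = -1

# Default movie geometry: 1152 x 648 px at 60.2 x 35.5 deg -> ~19.1 px/deg,
# half-diagonal eccentricity ~34.9 deg.
DEFAULT_FIELD_DEG = (60.2, 35.5)
DEFAULT_OUTER_ECC = float(np.hypot(DEFAULT_FIELD_DEG[0] / 2, DEFAULT_FIELD_DEG[1] / 2))


@dataclass(frozen=True)
class RegionMap:
    """Central disc + 5 annular rings x equal sectors.

    ``ring_edges`` holds 6 increasing eccentricity boundaries (deg): the
    disc covers [0, edges[0]]; annulus i covers (edges[i], edges[i+1]].
    Region ids: 0 is the disc; region ``1 + ring * n_sectors + sector``
    is sector ``sector`` of annulus ``ring``.  Sector 0 starts at angle 0
    (east) and angles increase counter-clockwise.
    """

    ring_edges: tuple[float, ...]
    n_sectors: int = 8
    _table: pd.DataFrame = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        edges = np.asarray(self.ring_edges, dtype=float)
        if edges.ndim != 1 or edges.size != 6:
            raise ValueError("ring_edges must hold 6 boundaries (disc + 5 rings)")
        if not np.all(np.diff(edges) > 0) or edges[0] <= 0:
            raise ValueError("ring_edges must be positive and strictly increasing")
        if self.n_sectors < 1:
            raise ValueError("n_sectors must be >= 1")
        object.__setattr__(self, "ring_edges", tuple(edges))
        object.__setattr__(self, "_table", self._build_table())

    # -- structure ---------------------------------------------------------
    @property
    def n_rings(self) -> int:
        return len(self.ring_edges) - 1

    @property
    def n_regions(self) -> int:
        return 1 + self.n_rings * self.n_sectors

    @property
    def region_ids(self) -> np.ndarray:
        return np.arange(self.n_regions)

    @property
    def outer_edge(self) -> float:
        return self.ring_edges[-1]

    def _build_table(self) -> pd.DataFrame:
        rows = [{"region": 0, "ring": -1, "sector": -1,
                 "centroid_x": 0.0, "centroid_y": 0.0, "side": "mid"}]
        edges = np.asarray(self.ring_edges)
        width = 2 * np.pi / self.n_sectors
        for ring in range(self.n_rings):
            # radial centroid of an annulus sector
            r0, r1 = edges[ring], edges[ring + 1]
            rbar = 2.0 / 3.0 * (r1**3 - r0**3) / (r1**2 - r0**2)
            for sector in range(self.n_sectors):
                mid = (sector + 0.5) * width
                cx = rbar * np.cos(mid)
                cy = rbar * np.sin(mid)
                if abs(np.cos(mid)) < 1e-12:
                    side = "mid"
                else:
                    side = "left" if cx < 0 else "right"
                rows.append({"region": 1 + ring * self.n_sectors + sector,
                             "ring": ring, "sector": sector,
                             "centroid_x": cx, "centroid_y": cy, "side": side})
        return pd.DataFrame(rows).set_index("region")

    def region_table(self) -> pd.DataFrame:
        """Per-region (ring, sector, centroid, side) lookup table."""
        return self._table.copy()

    def side_ids(self, side: str) -> np.ndarray:
        """Region ids whose sector centroid lies on ``side`` ('left'/'right')."""
        t = self._table
        return t.index[t["side"] == side].to_numpy()

    # -- geometry ----------------------------------------------------------
    def label_image(
        self,
        shape: tuple[int, int],
        ppd: float,
        gaze: tuple[float, float] = (0.0, 0.0),
    ) -> np.ndarray:
        """Label every pixel of an (h, w) frame with its region id.

        The map centre sits at the gaze position (degrees from the movie
        centre).  Pixels beyond the outer eccentricity edge get the
        ``BACKGROUND`` label; every pixel is labelled (totality holds for
        arbitrary gaze).
        """
        gx, gy = float(gaze[0]), float(gaze[1])
        if not (np.isfinite(gx) and np.isfinite(gy)):
            raise ValueError("gaze must be finite")
        h, w = shape
        cols = (np.arange(w) - (w - 1) / 2.0) / ppd - gx
        rows = ((h - 1) / 2.0 - np.arange(h)) / ppd - gy
        x = cols[None, :]
        y = rows[:, None]
        ecc = np.hypot(x, y)
        labels = np.full((h, w), BACKGROUND, dtype=np.int32)
        edges = np.asarray(self.ring_edges)
        inside = ecc <= edges[-1]
        disc = ecc <= edges[0]
        labels[disc] = 0
        annular = inside & ~disc
        if np.any(annular):
            ring = np.searchsorted(edges, ecc[annular], side="left") - 1
            ang = np.mod(np.arctan2(np.broadcast_to(y, ecc.shape)[annular],
                                    np.broadcast_to(x, ecc.shape)[annular]),
                         2 * np.pi)
            sector = np.minimum((ang / (2 * np.pi) * self.n_sectors).astype(int),
                                self.n_sectors - 1)
            labels[annular] = 1 + ring * self.n_sectors + sector
        return labels


@dataclass(frozen=True)
class PositionedRegionMap:
    """A RegionMap bound to one gaze position."""

    base: RegionMap
    gaze: tuple[float, float]

    def label_image(self, shape: tuple[int, int], ppd: float) -> np.ndarray:
        return self.base.label_image(shape, ppd, gaze=self.gaze)


def recenter(region_map: RegionMap, gaze: tuple[float, float]) -> PositionedRegionMap:
    """Translate the map centre to ``gaze`` (deg relative to movie centre)."""
    gx, gy = float(gaze[0]), float(gaze[1])
    if not (np.isfinite(gx) and np.isfinite(gy)):
        raise ValueError("gaze must be finite")
    return PositionedRegionMap(region_map, (gx, gy))


def build_region_map(
    ring_edges: tuple[float, ...] | None = None,
    n_sectors: int = 8,
    inner_ecc: float = 1.5,
    outer_ecc: float = DEFAULT_OUTER_ECC,
) -> RegionMap:
    """Build the default tessellation: disc + 5 rings x ``n_sectors``.

    When ``ring_edges`` is not given, six boundaries are geometrically
    spaced from ``inner_ecc`` (disc radius) to ``outer_ecc`` (the movie's
    half-diagonal), so ring area grows with eccentricity the way cortical
    magnification shrinks.
    """
    if ring_edges is None:
        ring_edges = tuple(np.geomspace(inner_ecc, outer_ecc, 6))
    return RegionMap(ring_edges=tuple(float(e) for e in ring_edges),
                     n_sectors=n_sectors)


# ---------------------------------------------------------------------------
# Event matrices


@dataclass
class EventMatrix:
    """Per-region signed luminance-change series at the movie rate.

    ``values[k, r]`` is the luminance change (cd/m^2) of region ``r`` at
    frame transition ``k`` (frame k -> k+1); ``times[k]`` the transition
    time in seconds.  Rows where gaze was purged are flagged in
    ``missing``.
    """

    times: np.ndarray
    values: np.ndarray
    region_ids: np.ndarray
    missing: np.ndarray = None
    rate: float = 25.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.region_ids = np.asarray(self.region_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (time x regions)")
        if self.values.shape != (self.times.size, self.region_ids.size):
            raise ValueError("values shape must be (len(times), len(region_ids))")
        if self.missing is None:
            self.missing = np.zeros(self.times.size, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)

    @property
    def n_regions(self) -> int:
        return self.region_ids.size

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class SaliencySummary:
    """Counts and mean magnitudes of supra-threshold luminance changes per side."""

    n_left: int
    n_right: int
    amp_left: float
    amp_right: float
    threshold: float

    @property
    def n_diff(self) -> int:
        """Right minus left event count."""
        return self.n_right - self.n_left

    @property
    def amp_diff(self) -> float:
        """Right minus left mean event magnitude."""
        return self.amp_right - self.amp_left


def extract_events(
    frames: np.ndarray,
    gaze: np.ndarray,
    region_map: RegionMap,
    ppd: float,
    gaze_missing: np.ndarray | None = None,
    rate: float = 25.0,
) -> EventMatrix:
    """Extract gaze-contingent per-region luminance changes from a frame stack.

    ``frames`` is (n_frames, h, w) in cd/m^2 at the movie rate, ``gaze``
    (n_frames, 2) in degrees.  For transition k the map is re-centred on
    the gaze at frame k+1 and the change is the difference of region mean
    luminance between frames k+1 and k under that single labelling.
    Regions with no on-frame pixels contribute 0.
    """
    frames = np.asarray(frames, dtype=float)
    gaze = np.asarray(gaze, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must be a (n_frames, h, w) stack")
    if gaze.shape != (frames.shape[0], 2):
        raise ValueError("gaze must be (n_frames, 2), aligned with frames")
    n_frames, h, w = frames.shape
    n_trans = n_frames - 1
    n_reg = region_map.n_regions
    values = np.zeros((n_trans, n_reg))
    missing = np.zeros(n_trans, dtype=bool)
    if gaze_missing is not None:
        gaze_missing = np.asarray(gaze_missing, dtype=bool)
    for k in range(n_trans):
        if gaze_missing is not None and (gaze_missing[k] or gaze_missing[k + 1]):
            missing[k] = True
            continue
        g = gaze[k + 1]
        if not np.all(np.isfinite(g)):
            missing[k] = True
            continue
        labels = region_map.label_image((h, w), ppd, gaze=g)
        flat = labels.ravel() + 1  # background -> 0
        counts = np.bincount(flat, minlength=n_reg + 1)[1:]
        s_prev = np.bincount(flat, weights=frames[k].ravel(), minlength=n_reg + 1)[1:]
        s_next = np.bincount(flat, weights=frames[k + 1].ravel(), minlength=n_reg + 1)[1:]
        ok = counts > 0
        values[k, ok] = (s_next[ok] - s_prev[ok]) / counts[ok]
    times = (np.arange(n_trans) + 1) / rate
    return EventMatrix(times=times, values=values,
                       region_ids=region_map.region_ids, missing=missing, rate=rate)


def summarize_saliency(
    events: EventMatrix,
    region_map: RegionMap,
    threshold: float = 5.0,
) -> SaliencySummary:
    """Count supra-threshold changes (|change| > threshold, strict) per side.

    The side of a region is the sign of its sector-centroid x coordinate;
    strictly midline regions (the central disc) belong to neither side.
    Rows flagged missing are ignored.
    """
    if events.n_regions != region_map.n_regions:
        raise ValueError("events not aligned with region map")
    vals = events.values[~events.missing]
    out = {}
    for side in ("left", "right"):
        ids = region_map.side_ids(side)
        v = np.abs(vals[:, ids])
        supra = v > threshold
        n = int(supra.sum())
        amp = float(v[supra].mean()) if n else 0.0
        out[side] = (n, amp)
    return SaliencySummary(n_left=out["left"][0], n_right=out["right"][0],
                           amp_left=out["left"][1], amp_right=out["right"][1],
                           threshold=threshold)
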