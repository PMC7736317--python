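"""Single-vessel morphometry and intravascular velocimetry.

From a blood mask: topology-preserving skeletonisation into
branch-to-branch centerline segments with per-pixel inner radii
(Euclidean distance transform), per-segment inner diameters with a
junction exclusion zone, and vessel density as segments per analyzable
area.  From fast time-lapses: centroid tracking of unlabeled-cell
shadows (intensity deficits moving through the labeled plasma) and
per-vessel / field mean speeds, paired with diameters for
velocity-vs-diameter phenotyping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import skeletonize

__all__ = [
    "VesselSkeleton",
    "SkeletonSegment",
    "CellTrack",
    "TrackingParams",
    "skeletonize_vessels",
    "vessel_diameters",
    "vessel_density",
    "track_cells",
    "cell_velocities",
    "DiameterResult",
    "VelocityResult",
]


# ---------------------------------------------------------------------------
# Skeletons
# ---------------------------------------------------------------------------

@dataclass
class SkeletonSegment:
    """One branch-to-branch centerline chain."""

    segment_id: int
    pixels: np.ndarray  # (N, 2) array of (row, col), ordered along the chain
    radii_um: np.ndarray  # per-pixel inner radius
    length_um: float


@dataclass
class VesselSkeleton:
    segments: list[SkeletonSegment]
    branch_points: np.ndarray  # (M, 2) array of (row, col)
    pixel_size_um: float
    shape: tuple[int, int]

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def max_radius_um(self) -> float:
        if not self.segments:
            return 0.0
        return max(float(s.radii_um.max()) for s in self.segments)

    def all_pixels(self) -> tuple[np.ndarray, np.ndarray]:
        """(pixels, segment_ids) over every centerline pixel."""
        px = np.concatenate([s.pixels for s in self.segments])
        ids = np.concatenate(
            [np.full(len(s.pixels), s.segment_id) for s in self.segments]
        )
        return px, ids


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _order_chain(pixels: set[tuple[int, int]]) -> list[tuple[int, int]]:
    """Order the pixels of a simple 8-connected chain by walking it."""
    nbr = {
        p: [
            (p[0] + dr, p[1] + dc)
            for dr, dc in _NEIGHBORS
            if (p[0] + dr, p[1] + dc) in pixels
        ]
        for p in pixels
    }
    ends = [p for p, ns in nbr.items() if len(ns) <= 1]
    start = min(ends) if ends else min(pixels)  # closed loop: arbitrary start
    order = [start]
    seen = {start}
    cur = start
    while True:
        nxt = [q for q in nbr[cur] if q not in seen]
        if not nxt:
            break
        # prefer 4-connected continuation to avoid corner-cutting
        nxt.sort(key=lambda q: (abs(q[0] - cur[0]) + abs(q[1] - cur[1]), q))
        cur = nxt[0]
        order.append(cur)
        seen.add(cur)
    return order


def skeletonize_vessels(blood_mask: np.ndarray, pixel_size_um: float) -> VesselSkeleton:
    """Skeletonise a blood mask into branch-to-branch segments.

    Centerlines come from topology-preserving thinning; branch points
    are skeleton pixels with more than two skeleton neighbors, and the
    chains left after their removal become the segments.  The inner
    radius at each centerline pixel is the Euclidean distance transform
    of the mask, in um.
    """
    mask = np.asarray(blood_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty blood mask")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    # pad by edge replication so thinning does not retract centerlines of
    # vessels that cross the field boundary; crop back afterwards
    pad = int(np.ceil(ndimage.distance_transform_edt(mask).max())) + 1
    padded = np.pad(mask, pad, mode="edge")
    skel = skeletonize(padded)[pad:-pad, pad:-pad]
    edt = (
        ndimage.distance_transform_edt(padded)[pad:-pad, pad:-pad] * pixel_size_um
    )

    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    nnbr = ndimage.convolve(skel.astype(int), kernel, mode="constant")
    branch = skel & (nnbr > 2)
    chains = skel & ~branch
    labels, n = ndimage.label(chains, structure=np.ones((3, 3), dtype=int))

    segments: list[SkeletonSegment] = []
    for lab in range(1, n + 1):
        pts = set(map(tuple, np.argwhere(labels == lab)))
        order = _order_chain(pts)
        px = np.asarray(order, dtype=int)
        steps = np.linalg.norm(np.diff(px, axis=0).astype(float), axis=1)
        length = float(steps.sum()) * pixel_size_um
        radii = edt[px[:, 0], px[:, 1]]
        segments.append(SkeletonSegment(lab - 1, px, radii, length))
    return VesselSkeleton(
        segments=segments,
        branch_points=np.argwhere(branch),
        pixel_size_um=pixel_size_um,
        shape=mask.shape,
    )


@dataclass
class DiameterResult:
    per_segment: pd.DataFrame  # segment_id, length_um, diameter_um
    field_mean_um: float


def vessel_diameters(skeleton: VesselSkeleton) -> DiameterResult:
    """Per-segment mean inner diameter (um) and the field-level mean.

    Diameter is twice the mean centerline radius over pixels farther
    than one maximal radius from any branch point; the exclusion zone
    avoids the diameter overestimate where lumens merge at
    bifurcations.  Segments entirely inside the zone are skipped with a
    warning.  The field mean is length-weighted.
    """
    if skeleton.n_segments == 0:
        raise ValueError("empty skeleton")
    excl_px = skeleton.max_radius_um / skeleton.pixel_size_um
    rows = []
    for seg in skeleton.segments:
        keep = np.ones(len(seg.pixels), dtype=bool)
        if skeleton.branch_points.size:
            d = np.linalg.norm(
                seg.pixels[:, None, :].astype(float)
                - skeleton.branch_points[None, :, :],
                axis=2,
            ).min(axis=1)
            keep = d > excl_px
        if not keep.any():
            warnings.warn(
                f"segment {seg.segment_id} shorter than the junction "
                "exclusion zone; skipped",
                stacklevel=2,
            )
            continue
        diam = 2.0 * float(seg.radii_um[keep].mean())
        rows.append(
            {
                "segment_id": seg.segment_id,
                "length_um": seg.length_um,
                "diameter_um": diam,
            }
        )
    df = pd.DataFrame(rows, columns=["segment_id", "length_um", "diameter_um"])
    if len(df) and df["length_um"].sum() > 0:
        fmean = float(np.average(df["diameter_um"], weights=df["length_um"]))
    elif len(df):
        fmean = float(df["diameter_um"].mean())
    else:
        fmean = np.nan
    return DiameterResult(per_segment=df, field_mean_um=fmean)


def vessel_density(skeleton: VesselSkeleton, analyzable_area_mm2: float) -> float:
    """Vessel density in 1/mm^2: skeleton segments per analyzable area.

    The counting unit is the branch-to-branch segment; the analyzable
    area is blood + tissue, excluding bone and background.
    """
    if analyzable_area_mm2 <= 0:
        raise ValueError("analyzable area must be positive")
    return skeleton.n_segments / analyzable_area_mm2


# ---------------------------------------------------------------------------
# Cell tracking
# ---------------------------------------------------------------------------

@dataclass
class CellTrack:
    """Centroid trajectory of one moving intravascular cell."""

    track_id: int
    frames: np.ndarray  # consecutive frame indices
    times_s: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        if self.frames.size and np.any(np.diff(self.frames) != 1):
            raise ValueError("track frames must be consecutive")

    def __len__(self) -> int:
        return self.frames.size

    @property
    def path_length_um(self) -> float:
        return float(
            np.sum(np.hypot(np.diff(self.x_um), np.diff(self.y_um)))
        )

    @property
    def elapsed_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0])

    @property
    def mean_speed_mm_s(self) -> float:
        if self.elapsed_s == 0:
            raise ValueError("track has zero elapsed time")
        return self.path_length_um / self.elapsed_s / 1000.0

    def median_position_um(self) -> tuple[float, float]:
        return float(np.median(self.x_um)), float(np.median(self.y_um))


@dataclass
class TrackingParams:
    """Detection and linking settings for cell-shadow tracking.

    ``gate_um`` is the nearest-neighbor linking radius; choose the frame
    rate so the per-frame displacement stays below it (ideally below
    half of it).  ``deficit_frac`` is the relative intensity drop below
    the frame's median lumen intensity that counts as a cell shadow.
    """

    gate_um: float = 20.0
    deficit_frac: float = 0.3
    min_area_px: int = 3
    min_track_length: int = 3


def track_cells(stack, masks, params: TrackingParams | None = None, channel=0):
    """Detect and link unlabeled-cell shadows inside the blood mask.

    Per frame, pixels inside the lumen darker than
    ``(1 - deficit_frac)`` times the median lumen intensity are grouped
    into blobs; blob centroids are linked frame-to-frame by greedy
    nearest neighbor within the gate.  Tracks shorter than
    ``min_track_length`` points are discarded.
    """
    params = params or TrackingParams()
    if params.gate_um < stack.pixel_size_um:
        raise ValueError("linking gate smaller than one pixel")
    img = stack.channel(channel)
    lumen = masks.blood
    ps = stack.pixel_size_um
    times = stack.frame_times

    detections: list[np.ndarray] = []
    for k in range(stack.n_frames):
        frame = img[k]
        ref = float(np.median(frame[lumen]))
        blob = lumen & (frame < (1.0 - params.deficit_frac) * ref)
        labels, n = ndimage.label(blob)
        cents = []
        if n:
            areas = ndimage.sum_labels(blob, labels, index=np.arange(1, n + 1))
            coms = ndimage.center_of_mass(blob, labels, index=np.arange(1, n + 1))
            for area, (r, c) in zip(areas, coms):
                if area >= params.min_area_px:
                    cents.append(((c + 0.5) * ps, (r + 0.5) * ps))
        detections.append(np.asarray(cents, dtype=float).reshape(-1, 2))

    # greedy nearest-neighbor linking of consecutive frames
    finished: list[dict] = []
    active: list[dict] = []  # {"frames": [...], "xy": [...]}
    for k, dets in enumerate(detections):
        used = np.zeros(len(dets), dtype=bool)
        still_active = []
        for tr in active:
            last = tr["xy"][-1]
            best_j, best_d = -1, params.gate_um
            for j, p in enumerate(dets):
                if used[j]:
                    continue
                d = float(np.hypot(p[0] - last[0], p[1] - last[1]))
                if d <= best_d:
                    best_j, best_d = j, d
            if best_j >= 0:
                used[best_j] = True
                tr["frames"].append(k)
                tr["xy"].append(tuple(dets[best_j]))
                still_active.append(tr)
            else:
                finished.append(tr)
        active = still_active
        for j, p in enumerate(dets):
            if not used[j]:
                active.append({"frames": [k], "xy": [tuple(p)]})
    finished.extend(active)

    tracks = []
    tid = 0
    for tr in finished:
        if len(tr["frames"]) < params.min_track_length:
            continue
        fr = np.asarray(tr["frames"])
        xy = np.asarray(tr["xy"])
        tracks.append(
            CellTrack(tid, fr, times[fr], xy[:, 0], xy[:, 1])
        )
        tid += 1
    return tracks


@dataclass
class VelocityResult:
    per_vessel: pd.DataFrame  # segment_id, diameter_um, mean_velocity_mm_s, n_tracks
    field_mean_mm_s: float
    track_speeds_mm_s: np.ndarray

    def plot_velocity_diameter(self, ax=None):
        """Scatter of per-vessel mean cell velocity against inner diameter."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(
            self.per_vessel["diameter_um"],
            self.per_vessel["mean_velocity_mm_s"],
            s=25,
            color="tab:red",
        )
        ax.set_xlabel("inner diameter (um)")
        ax.set_ylabel("mean cell velocity (mm/s)")
        return ax


def cell_velocities(
    tracks: list[CellTrack], skeleton: VesselSkeleton
) -> VelocityResult:
    """Per-vessel and field mean cell speeds (mm/s).

    Per-track speed is path length over elapsed time; each track is
    assigned to the skeleton segment whose centerline pixel is nearest
    to the track's median position, giving per-vessel (velocity,
    diameter) pairs for velocity-diameter scatter analyses.  Per-vessel
    means are weighted by track duration, so a cell whose trajectory
    fragments into several tracks is not over-counted; the field mean
    is the unweighted mean over vessels.
    """
    if not tracks:
        raise ValueError("no tracks to summarise")
    speeds = np.array([t.mean_speed_mm_s for t in tracks])
    durations = np.array([t.elapsed_s for t in tracks])
    px, ids = skeleton.all_pixels()
    center_um = (px[:, ::-1].astype(float) + 0.5) * skeleton.pixel_size_um  # (x, y)
    assign = []
    for t in tracks:
        x, y = t.median_position_um()
        d2 = (center_um[:, 0] - x) ** 2 + (center_um[:, 1] - y) ** 2
        assign.append(int(ids[np.argmin(d2)]))
    diam = vessel_diameters(skeleton).per_segment.set_index("segment_id")[
        "diameter_um"
    ]
    df = pd.DataFrame(
        {"segment_id": assign, "speed": speeds, "duration": durations}
    )
    grouped = df.groupby("segment_id").apply(
        lambda grp: pd.Series(
            {
                "mean_velocity_mm_s": np.average(
                    grp["speed"], weights=grp["duration"]
                ),
                "n_tracks": len(grp),
            }
        ),
        include_groups=False,
    )
    per_vessel = grouped.reset_index()
    per_vessel["n_tracks"] = per_vessel["n_tracks"].astype(int)
    per_vessel["diameter_um"] = per_vessel["segment_id"].map(diam)
    per_vessel = per_vessel[
        ["segment_id", "diameter_um", "mean_velocity_mm_s", "n_tracks"]
    ]
    return VelocityResult(
        per_vessel=per_vessel,
        field_mean_mm_s=float(per_vessel["mean_velocity_mm_s"].mean()),
        track_speeds_mm_s=speeds,
    )
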