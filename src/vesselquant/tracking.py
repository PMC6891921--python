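"""Leukocyte (PMN) detection, linking, speed, and extravasation fate.

Neutrophils perfused through microvessels are imaged as bright spots in
their own channel over a short time-lapse (the study used five 2-min
frames).  The pipeline here detects spots per frame, links them across
frames by greedy mutual-nearest-neighbour matching, measures each
track's mean speed, and classifies its fate relative to the vessel mask
at the final frame:

* ``intravascular`` — final position inside the vessel footprint and
  farther than the contact distance from its boundary;
* ``transmigrating`` — final position within the contact distance of the
  boundary, on either side (in contact with the endothelium);
* ``extravasated``  — final position outside the footprint and beyond
  the contact distance (fully resident in the extravascular space).

Positions are stored as (t_s, x_px, y_px) with x = column and y = row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .stack import BinaryMask

__all__ = [
    "ParticleTrack",
    "ExtravasationSummary",
    "FATES",
    "detect_particles",
    "link_tracks",
    "mean_speed",
    "signed_boundary_distance",
    "classify_track",
    "summarize",
]

FATES = ("intravascular", "transmigrating", "extravasated")


@dataclass
class ParticleTrack:
    """Time-indexed centroids of one tracked particle."""

    track_id: int
    positions: list[tuple[float, float, float]]  # (t_s, x_px, y_px)
    fate: str | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [p[0] for p in self.positions]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("track timestamps must be strictly increasing")
        if self.fate is not None and self.fate not in FATES:
            raise ValueError(f"unknown fate {self.fate!r}")

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    @property
    def final_xy(self) -> tuple[float, float]:
        return self.positions[-1][1], self.positions[-1][2]


def detect_particles(
    frame: np.ndarray, intensity_threshold: float, min_spot_px: int = 3
) -> np.ndarray:
    """Intensity-weighted centroids of above-threshold spots.

    Returns an ``(N, 2)`` array of (x, y) centroids; empty when the frame
    holds no spot of at least ``min_spot_px`` pixels above threshold.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("detect_particles expects a single 2-D frame")
    labels = measure.label(frame > intensity_threshold, connectivity=2)
    centroids = []
    for region in measure.regionprops(labels, intensity_image=frame):
        if region.area < min_spot_px:
            continue
        cy, cx = region.centroid_weighted
        centroids.append((float(cx), float(cy)))
    return np.array(centroids, dtype=float).reshape(-1, 2)


def link_tracks(
    detections: list[np.ndarray],
    max_disp_px: float,
    frame_interval_s: float,
) -> list[ParticleTrack]:
    """Greedy mutual-nearest-neighbour frame-to-frame linking.

    Pairs are accepted in order of increasing distance (ties broken by
    detection index), each detection used once, and only below
    ``max_disp_px``; leftovers start new tracks and unmatched tracks
    terminate.  Deterministic for a given input.
    """
    if len(detections) < 2:
        raise ValueError("linking needs at least 2 frames of detections")
    tracks: list[ParticleTrack] = []
    active: dict[int, ParticleTrack] = {}
    next_id = 0

    def _new_track(t_s: float, x: float, y: float) -> None:
        nonlocal next_id
        tr = ParticleTrack(track_id=next_id, positions=[(t_s, x, y)])
        tracks.append(tr)
        active[next_id] = tr
        next_id += 1

    first = np.asarray(detections[0], dtype=float).reshape(-1, 2)
    for x, y in first:
        _new_track(0.0, float(x), float(y))

    for k in range(1, len(detections)):
        t_s = k * frame_interval_s
        dets = np.asarray(detections[k], dtype=float).reshape(-1, 2)
        ids = sorted(active)
        if ids and len(dets):
            prev = np.array([active[i].final_xy for i in ids])
            dist = np.linalg.norm(prev[:, None, :] - dets[None, :, :], axis=2)
            pairs = sorted(
                ((dist[i, j], i, j) for i in range(len(ids)) for j in range(len(dets))),
                key=lambda t: (t[0], t[1], t[2]),
            )
            used_tr: set[int] = set()
            used_det: set[int] = set()
            for d, i, j in pairs:
                if d > max_disp_px:
                    break
                if i in used_tr or j in used_det:
                    continue
                used_tr.add(i)
                used_det.add(j)
                active[ids[i]].positions.append((t_s, float(dets[j, 0]), float(dets[j, 1])))
        else:
            used_tr, used_det = set(), set()
        # unmatched active tracks terminate
        for pos, tid in enumerate(ids):
            if pos not in used_tr:
                del active[tid]
        for j in range(len(dets)):
            if j not in used_det:
                _new_track(t_s, float(dets[j, 0]), float(dets[j, 1]))
    return tracks


def mean_speed(track: ParticleTrack, pixel_size_um: float) -> float | None:
    """Mean speed in um/min: summed step displacements over elapsed time.

    A single-position track has no defined speed; ``None`` is returned
    and the track flagged.
    """
    if track.n_frames < 2:
        track.flags.append("single_position")
        return None
    pos = np.array([(x, y) for _, x, y in track.positions])
    path_um = float(np.sum(np.linalg.norm(np.diff(pos, axis=0), axis=1))) * pixel_size_um
    elapsed_min = (track.positions[-1][0] - track.positions[0][0]) / 60.0
    return path_um / elapsed_min


def signed_boundary_distance(mask: BinaryMask, x: float, y: float) -> float:
    """Distance (px) to the mask boundary: positive inside, negative outside.

    Bilinear interpolation of the inside/outside distance transforms at
    a sub-pixel position.
    """
    inside = ndimage.distance_transform_edt(mask.data)
    outside = ndimage.distance_transform_edt(~mask.data)
    sd = inside - outside
    return float(ndimage.map_coordinates(sd, [[y], [x]], order=1, mode="nearest")[0])


def classify_track(
    track: ParticleTrack, vessel_mask: BinaryMask, contact_dist_px: float = 2.0
) -> str:
    """Assign a fate from the track's final position (endpoint scoring)."""
    x, y = track.final_xy
    h, w = vessel_mask.data.shape
    if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
        raise ValueError(f"track {track.track_id}: final position ({x}, {y}) outside image")
    sd = signed_boundary_distance(vessel_mask, x, y)
    if abs(sd) <= contact_dist_px:
        fate = "transmigrating"
    elif sd < 0:
        fate = "extravasated"
    else:
        fate = "intravascular"
    track.fate = fate
    return fate


@dataclass
class ExtravasationSummary:
    n_tracks: int
    pct_extravasated: float
    pct_transmigrating: float
    mean_speed_um_min: float | None
    sem_speed_um_min: float | None
    speeds_um_min: list[float] = field(default_factory=list)


def summarize(tracks: list[ParticleTrack], pixel_size_um: float = 1.0) -> ExtravasationSummary:
    """Cohort percentages and the speed distribution (mean +/- s.e.m.)."""
    classified = [t for t in tracks if t.fate is not None]
    if not classified:
        raise ValueError("no classified tracks to summarize")
    n = len(classified)
    n_ex = sum(t.fate == "extravasated" for t in classified)
    n_tm = sum(t.fate == "transmigrating" for t in classified)
    speeds = [s for t in classified if (s := mean_speed(t, pixel_size_um)) is not None]
    mean_v = float(np.mean(speeds)) if speeds else None
    sem_v = float(np.std(speeds, ddof=1) / np.sqrt(len(speeds))) if len(speeds) > 1 else None
    return ExtravasationSummary(
        n_tracks=n,
        pct_extravasated=100.0 * n_ex / n,
        pct_transmigrating=100.0 * n_tm / n,
        mean_speed_um_min=mean_v,
        sem_speed_um_min=sem_v,
        speeds_um_min=speeds,
    )
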