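"""Synthetic confocal-like phantoms with exact ground truth.

No raw microscopy is distributed with the study this package quantifies,
so every downstream stage is validated against phantoms: fluorescent
tubular networks of known topology and radii on a dark background, a
dextran channel whose extravascular intensity rises linearly in time at
a rate set by a known permeability, and point-like migrating particles
with known per-frame positions and known fate.

Geometry is analytic: a pixel belongs to a vessel branch iff its centre
lies within the branch radius of the branch polyline (Euclidean), so the
footprint, area fraction and capsule perimeter are all checkable in
closed form.  Noise is additive Gaussian clipped at zero, and identical
spec + seed always reproduces bit-identical images and truth.

Phantoms are 2-D projections by default — the study's morphometry runs
on maximum-intensity projections — with an optional thin 3-D mode that
replicates the footprint across a few z-slices for projection testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import permeability as _perm
from .stack import BinaryMask, ImageStack
from .tracking import ParticleTrack, FATES

__all__ = [
    "TubeBranch",
    "PhantomSpec",
    "LeakageSpec",
    "MotionSpec",
    "PhantomTruth",
    "generate_network_phantom",
    "simulate_leakage_series",
    "simulate_pmn_motion",
    "random_tree_network",
    "single_vessel_phantom",
    "pmn_cohort_phantom",
]


@dataclass(frozen=True)
class TubeBranch:
    """One vessel branch: a polyline of (row, col) control points + radius."""

    points: tuple[tuple[float, float], ...]
    radius_px: float

    def length_px(self) -> float:
        pts = np.asarray(self.points, dtype=float)
        return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


@dataclass
class PhantomSpec:
    """Recipe for a tubular-network phantom."""

    image_shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 1.0
    branches: list[TubeBranch] = field(default_factory=list)
    vessel_intensity: float = 200.0
    background_intensity: float = 20.0
    noise_sigma: float = 0.0
    n_slices: int = 1  # >1 replicates the footprint into a thin z-stack
    z_step_um: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_shape
        if self.vessel_intensity <= self.background_intensity:
            raise ValueError("vessel_intensity must exceed background_intensity")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        for i, b in enumerate(self.branches):
            if b.radius_px < 1:
                raise ValueError(f"branch {i}: radius must be >= 1 px")
            if len(b.points) < 2:
                raise ValueError(f"branch {i}: polyline needs >= 2 points")
            for r, c in b.points:
                if not (0 <= r <= h - 1 and 0 <= c <= w - 1):
                    raise ValueError(
                        f"branch {i}: control point ({r}, {c}) outside image bounds {h}x{w}"
                    )


@dataclass
class LeakageSpec:
    """Forward model for a dextran leakage time-lapse."""

    P_true_cm_per_s: float = 1e-6
    frame_interval_s: float = 300.0  # the study captured 3 x 5 min intervals
    n_frames: int = 4
    I_V0: float = 200.0
    I_T0: float = 20.0
    noise_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.P_true_cm_per_s < 0:
            raise ValueError("P_true must be non-negative")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.I_V0 <= self.I_T0:
            raise ValueError("I_V0 must exceed I_T0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")


@dataclass
class MotionSpec:
    """Forward model for a PMN migration time-lapse.

    Per-frame displacement magnitude is ``speed * frame_interval``; the
    requested fate is realised geometrically against the vessel mask
    (see :mod:`vesselquant.tracking` for the fate definitions).
    """

    n_particles: int = 10
    speeds_um_min: tuple[float, ...] = ()
    fates: tuple[str, ...] = ()
    frame_interval_s: float = 120.0  # the study captured 5 x 2 min intervals
    n_frames: int = 5
    contact_dist_px: float = 2.0
    min_separation_px: float = 40.0  # per frame; > two max steps, so cohorts never swap
    spot_sigma_px: float = 2.0
    spot_amplitude: float = 150.0
    background_intensity: float = 5.0
    noise_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_particles < 1:
            raise ValueError("need at least 1 particle")
        if len(self.speeds_um_min) != self.n_particles or len(self.fates) != self.n_particles:
            raise ValueError("speeds_um_min and fates must each have n_particles entries")
        if any(s < 0 for s in self.speeds_um_min):
            raise ValueError("speeds must be non-negative")
        for f in self.fates:
            if f not in FATES:
                raise ValueError(f"unknown fate {f!r}")


@dataclass
class PhantomTruth:
    """Exact ground truth accompanying a phantom."""

    mask: BinaryMask
    n_junctions: int
    n_endpoints: int
    branch_lengths_px: list[float]
    branch_radii_px: list[float]
    area_fraction: float
    pixel_size_um: float
    P_true_cm_per_s: float | None = None
    tracks: list[ParticleTrack] = field(default_factory=list)
    fates: list[str] = field(default_factory=list)

    @property
    def n_branches(self) -> int:
        return len(self.branch_lengths_px)

    @property
    def connectivity_ratio(self) -> float:
        if self.n_endpoints == 0:
            return float("inf") if self.n_junctions > 0 else 0.0
        return self.n_junctions / self.n_endpoints


# ---------------------------------------------------------------------------
# network phantom


def _rasterize_branch(shape: tuple[int, int], branch: TubeBranch) -> np.ndarray:
    """Pixels whose centres lie within radius of the branch polyline."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    r = branch.radius_px
    pts = np.asarray(branch.points, dtype=float)
    for a, b in zip(pts, pts[1:]):
        lo = np.maximum(np.floor(np.minimum(a, b) - r - 1).astype(int), 0)
        hi = np.minimum(np.ceil(np.maximum(a, b) + r + 1).astype(int), [h - 1, w - 1])
        if np.any(hi < lo):
            continue
        rows = np.arange(lo[0], hi[0] + 1)
        cols = np.arange(lo[1], hi[1] + 1)
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        p = np.stack([rr, cc], axis=-1).astype(float)
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            d = np.linalg.norm(p - a, axis=-1)
        else:
            t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
            proj = a + t[..., None] * ab
            d = np.linalg.norm(p - proj, axis=-1)
        mask[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1] |= d <= r
    return mask


def _topology_from_branches(branches: list[TubeBranch]) -> tuple[int, int]:
    """Junction/endpoint counts from the incidence of branch termini."""
    degree: dict[tuple[int, int], int] = {}
    for b in branches:
        for p in (b.points[0], b.points[-1]):
            key = (int(round(p[0] * 2)), int(round(p[1] * 2)))
            degree[key] = degree.get(key, 0) + 1
    n_junctions = sum(1 for d in degree.values() if d >= 3)
    n_endpoints = sum(1 for d in degree.values() if d == 1)
    return n_junctions, n_endpoints


def generate_network_phantom(spec: PhantomSpec) -> tuple[ImageStack, PhantomTruth]:
    """Rasterize a tube network into an EC-channel image plus exact truth."""
    spec.validate()
    h, w = spec.image_shape
    mask = np.zeros((h, w), dtype=bool)
    for b in spec.branches:
        mask |= _rasterize_branch((h, w), b)

    rng = np.random.default_rng(spec.seed)
    base = np.where(mask, spec.vessel_intensity, spec.background_intensity).astype(float)
    if spec.n_slices > 1:
        base = np.repeat(base[None], spec.n_slices, axis=0)
    if spec.noise_sigma > 0:
        base = base + rng.normal(0.0, spec.noise_sigma, size=base.shape)
    img = np.clip(base, 0.0, None)

    n_j, n_e = _topology_from_branches(spec.branches)
    truth = PhantomTruth(
        mask=BinaryMask(mask, pixel_size_um=spec.pixel_size_um, provenance={"source": "phantom"}),
        n_junctions=n_j,
        n_endpoints=n_e,
        branch_lengths_px=[b.length_px() for b in spec.branches],
        branch_radii_px=[b.radius_px for b in spec.branches],
        area_fraction=float(np.count_nonzero(mask)) / float(mask.size),
        pixel_size_um=spec.pixel_size_um,
    )
    stack = ImageStack(
        channels={"EC": img},
        pixel_size_um=spec.pixel_size_um,
        z_step_um=spec.z_step_um if spec.n_slices > 1 else None,
    )
    return stack, truth


def random_tree_network(
    seed: int,
    image_shape: tuple[int, int] = (256, 256),
    n_attachments: int = 3,
    radius_choices_px: tuple[float, ...] = (3.5, 4.5),
    branch_len_range_px: tuple[float, float] = (70.0, 120.0),
    min_piece_px: float = 55.0,
    **spec_kwargs,
) -> PhantomSpec:
    """A seeded random vessel tree with clean, recoverable topology.

    Grows straight side-branches off a central trunk.  Each attachment
    splits the carrying branch at the attachment point, so the spec's
    branch list is already the node-to-node segmentation the skeleton
    should recover: junction/endpoint counts follow from terminus
    incidence and per-branch lengths are directly comparable.

    Geometry is kept benign on purpose — wide branching angles, branch
    pieces of at least ``min_piece_px``, generous clearance between
    unrelated branches — and radii are drawn on the half-pixel grid,
    where the rasterized tube width equals the nominal diameter exactly
    (an integer radius r rasterizes to a 2r+1-px-wide footprint).
    """
    rng = np.random.default_rng(seed)
    h, w = image_shape
    margin = 14.0

    def _in_bounds(p: np.ndarray) -> bool:
        return margin <= p[0] <= h - 1 - margin and margin <= p[1] <= w - 1 - margin

    # Branch directions stay near the axis grid (small jitter only), and
    # side branches leave at right angles.  Two digital artifacts make
    # oblique geometry a poor ground truth: the 1/sqrt2 geodesic step
    # metric reads up to ~8% long on lines near 22.5 degrees, and the
    # medial-axis branch point of an acute junction is displaced along
    # the parent by about one tube radius (a right-angle T displaces it
    # by only ~r/4).
    jitter = np.deg2rad(2.0)

    # trunk through the middle at a near-horizontal angle
    ang = rng.uniform(-jitter, jitter)
    centre = np.array([h / 2.0, w / 2.0])
    direction = np.array([np.sin(ang), np.cos(ang)])
    half = min(h, w) / 2.0 - margin
    a, b = centre - direction * half, centre + direction * half
    radius = float(rng.choice(radius_choices_px))
    # branch entries: [start, end, radius]; split in place on attachment
    branch_list: list[list] = [[a, b, radius]]

    made = 0
    for _ in range(300):
        if made >= n_attachments:
            break
        seg_idx = int(rng.integers(len(branch_list)))
        pa, pb, prad = branch_list[seg_idx]
        seg_vec = pb - pa
        seg_len = float(np.linalg.norm(seg_vec))
        if seg_len < 2 * min_piece_px:
            continue
        pdir = seg_vec / seg_len
        t = rng.uniform(min_piece_px / seg_len, 1.0 - min_piece_px / seg_len)
        origin = pa + t * seg_vec
        side = rng.choice([-1.0, 1.0])
        parent_ang = float(np.arctan2(pdir[0], pdir[1]))
        turn = side * np.deg2rad(90.0)
        grid = np.round((parent_ang + turn) / (np.pi / 4)) * (np.pi / 4)
        new_ang = grid + rng.uniform(-jitter, jitter)
        new_dir = np.array([np.sin(new_ang), np.cos(new_ang)])
        length = rng.uniform(*branch_len_range_px)
        end = origin + new_dir * length
        if not _in_bounds(end):
            continue
        new_radius = float(rng.choice(radius_choices_px))
        # the far part of the new branch must clear all unrelated geometry
        clearance = new_radius + max(radius_choices_px) + 8.0
        far_start = origin + new_dir * min(clearance, length / 2)
        ok = True
        for k, (qa, qb, _qr) in enumerate(branch_list):
            if k == seg_idx:
                continue  # touches the carrying branch by construction
            if _min_segment_distance(far_start, end, qa, qb) < clearance:
                ok = False
                break
        # junctions and free termini must stay well separated
        anchors = [q for qa, qb, _qr in branch_list for q in (qa, qb)]
        if ok and any(np.linalg.norm(origin - q) < min_piece_px * 0.8 for q in anchors):
            ok = False
        if ok and any(np.linalg.norm(end - q) < min_piece_px * 0.8 for q in anchors):
            ok = False
        if not ok:
            continue
        branch_list[seg_idx] = [pa, origin, prad]
        branch_list.append([origin, pb, prad])
        branch_list.append([origin, end, new_radius])
        made += 1

    branches = [
        TubeBranch(points=(tuple(s), tuple(e)), radius_px=r) for s, e, r in branch_list
    ]
    return PhantomSpec(image_shape=image_shape, branches=branches, seed=seed, **spec_kwargs)


def single_vessel_phantom(
    radius_px: float = 10.0,
    image_shape: tuple[int, int] = (256, 256),
    **spec_kwargs,
) -> PhantomSpec:
    """One straight perfused vessel crossing the field horizontally.

    This is the geometry used for leakage simulations: a single patent
    vessel whose perimeter-to-tissue ratio is low enough that even fast
    leakage stays in the linear (far-from-saturation) regime over a
    15-minute series.
    """
    h, w = image_shape
    margin = 10.0 + radius_px
    pts = ((h / 2.0, margin), (h / 2.0, w - 1 - margin))
    return PhantomSpec(
        image_shape=image_shape,
        branches=[TubeBranch(points=pts, radius_px=radius_px)],
        **spec_kwargs,
    )


def pmn_cohort_phantom(
    seed: int,
    n_intravascular: int = 4,
    n_transmigrating: int = 3,
    n_extravasated: int = 3,
    speed_range_um_min: tuple[float, float] = (2.0, 8.0),
    noise_sigma: float = 0.0,
) -> tuple[ImageStack, PhantomTruth, list[ParticleTrack]]:
    """A wide-vessel field with a mixed-fate, non-crossing PMN cohort.

    The vessel is broad (28 px radius in a 384 px field) so that every
    fate class has room at the 40 px cohort separation; speeds are drawn
    uniformly from ``speed_range_um_min`` (physiological crawling speeds
    of a few um/min over five 2-min frames).
    """
    spec = single_vessel_phantom(radius_px=28.0, image_shape=(384, 384))
    _, truth = generate_network_phantom(spec)
    n = n_intravascular + n_transmigrating + n_extravasated
    rng = np.random.default_rng(seed)
    speeds = tuple(float(v) for v in rng.uniform(*speed_range_um_min, size=n))
    fates = tuple(
        ["intravascular"] * n_intravascular
        + ["transmigrating"] * n_transmigrating
        + ["extravasated"] * n_extravasated
    )
    motion = MotionSpec(
        n_particles=n,
        speeds_um_min=speeds,
        fates=fates,
        noise_sigma=noise_sigma,
        seed=seed,
    )
    series, tracks = simulate_pmn_motion(truth, motion)
    return series, truth, tracks


def _min_segment_distance(a0, a1, b0, b1) -> float:
    """Minimum distance between two 2-D segments (sampled)."""
    ta = np.linspace(0.0, 1.0, 32)[:, None]
    pa = a0 + ta * (np.asarray(a1) - a0)
    tb = np.linspace(0.0, 1.0, 32)[:, None]
    pb = b0 + tb * (np.asarray(b1) - b0)
    return float(np.min(np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)))


# ---------------------------------------------------------------------------
# leakage phantom


def leakage_tissue_intensity(
    truth: PhantomTruth, leak: LeakageSpec, t_s: np.ndarray | float
) -> np.ndarray:
    """Noise-free extravascular intensity of the forward model at time t.

    With constant transendothelial flux the tissue mean rises linearly:
    ``I_T(t) = I_T0 + P * p_v * t * (I_V0 - I_T0) / A_T`` with p_v and
    A_T measured from the truth mask.
    """
    p_v, A_T = _perm.region_partition(truth.mask)
    rate = leak.P_true_cm_per_s * p_v * (leak.I_V0 - leak.I_T0) / A_T
    return leak.I_T0 + rate * np.asarray(t_s, dtype=float)


def simulate_leakage_series(truth: PhantomTruth, leak: LeakageSpec) -> ImageStack:
    """Dextran time-lapse with known permeability.

    Intravascular pixels hold I_V0 in every frame (the vessel acts as a
    reservoir); extravascular pixels follow the linear forward model.
    Raises if the tissue intensity would reach I_V0 within the series —
    the constant-flux approximation is then broken and the series should
    be shortened or P lowered.
    """
    leak.validate()
    if not truth.mask.data.any():
        raise ValueError("truth mask is empty")
    times = np.arange(leak.n_frames) * leak.frame_interval_s
    tissue = leakage_tissue_intensity(truth, leak, times)
    if np.any(tissue >= leak.I_V0):
        raise ValueError(
            "tissue intensity reaches I_V0 within the series; the constant-flux "
            "assumption is violated — shorten the series or lower P_true"
        )
    fg = truth.mask.data
    frames = np.empty((leak.n_frames, *fg.shape), dtype=float)
    for k in range(leak.n_frames):
        frames[k] = np.where(fg, leak.I_V0, tissue[k])
    rng = np.random.default_rng(leak.seed)
    if leak.noise_sigma > 0:
        frames = np.clip(frames + rng.normal(0.0, leak.noise_sigma, frames.shape), 0.0, None)
    truth.P_true_cm_per_s = leak.P_true_cm_per_s
    return ImageStack(
        channels={"dextran": frames},
        pixel_size_um=truth.pixel_size_um,
        frame_interval_s=leak.frame_interval_s,
    )


# ---------------------------------------------------------------------------
# motion phantom


def _signed_distance_field(mask: np.ndarray) -> np.ndarray:
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return inside - outside


def _sample_sd(sd: np.ndarray, p: np.ndarray) -> float:
    return float(ndimage.map_coordinates(sd, [[p[0]], [p[1]]], order=1, mode="nearest")[0])


def _pick_position(
    rng: np.random.Generator, sd: np.ndarray, lo: float, hi: float, margin: float
) -> np.ndarray:
    """Random (row, col) whose signed boundary distance lies in [lo, hi]."""
    h, w = sd.shape
    for _ in range(20000):
        p = rng.uniform([margin, margin], [h - 1 - margin, w - 1 - margin])
        if lo <= _sample_sd(sd, p) <= hi:
            return p
    raise ValueError(
        f"no position with boundary distance in [{lo}, {hi}]; the requested "
        "fate is geometrically impossible for this mask"
    )


def _walk_backward(
    rng: np.random.Generator,
    end: np.ndarray,
    step_px: float,
    n_steps: int,
    shape: tuple[int, int],
    margin: float,
) -> list[np.ndarray]:
    """Path of equal-length steps ending exactly at ``end`` (built backward)."""
    h, w = shape
    path = [end]
    heading = rng.uniform(0, 2 * np.pi)
    for _ in range(n_steps):
        for _try in range(100):
            cand = path[-1] + step_px * np.array([np.sin(heading), np.cos(heading)])
            if margin <= cand[0] <= h - 1 - margin and margin <= cand[1] <= w - 1 - margin:
                break
            heading = rng.uniform(0, 2 * np.pi)
        else:
            cand = path[-1]  # stationary fallback; only possible in tiny frames
        path.append(cand)
        heading += rng.normal(0.0, 0.4)
    return path[::-1]


def _walk_inside(
    rng: np.random.Generator,
    sd: np.ndarray,
    start: np.ndarray,
    step_px: float,
    n_steps: int,
    min_depth: float,
    margin: float = 8.0,
) -> list[np.ndarray]:
    """Random walk of equal steps that never leaves depth >= min_depth."""
    h, w = sd.shape
    path = [start]
    heading = rng.uniform(0, 2 * np.pi)
    for _ in range(n_steps):
        placed = False
        for _try in range(200):
            cand = path[-1] + step_px * np.array([np.sin(heading), np.cos(heading)])
            in_bounds = (
                margin <= cand[0] <= h - 1 - margin and margin <= cand[1] <= w - 1 - margin
            )
            if in_bounds and _sample_sd(sd, cand) >= min_depth:
                path.append(cand)
                placed = True
                break
            heading = rng.uniform(0, 2 * np.pi)
        if not placed:
            raise ValueError(
                "intravascular walk is stuck: vessel too narrow for the requested "
                "step length — reduce the speed or widen the vessel"
            )
        heading += rng.normal(0.0, 0.3)
    return path


def simulate_pmn_motion(
    truth: PhantomTruth, motion: MotionSpec
) -> tuple[ImageStack, list[ParticleTrack]]:
    """Render migrating particles with known positions and fates.

    Particles are Gaussian spots in a dedicated "PMN" channel.  Each
    particle moves exactly ``speed * frame_interval`` per frame; the
    final position realises the requested fate geometrically (with a
    half-pixel safety margin inside each fate band so the classifier's
    decision is unambiguous).  Raises when a fate cannot be realised on
    the given mask.
    """
    motion.validate()
    mask = truth.mask.data
    if not mask.any():
        raise ValueError("truth mask is empty")
    h, w = mask.shape
    sd = _signed_distance_field(mask)
    rng = np.random.default_rng(motion.seed)
    px = truth.pixel_size_um
    contact = motion.contact_dist_px

    placed_paths: list[np.ndarray] = []
    tracks: list[ParticleTrack] = []
    for i in range(motion.n_particles):
        speed = motion.speeds_um_min[i]
        fate = motion.fates[i]
        step_px = speed * (motion.frame_interval_s / 60.0) / px
        n_steps = motion.n_frames - 1
        for _attempt in range(250):
            if fate == "intravascular":
                depth = contact + 1.0
                start = _pick_position(rng, sd, depth + 1.0, np.inf, margin=8.0)
                path = _walk_inside(rng, sd, start, step_px, n_steps, min_depth=depth)
            elif fate == "transmigrating":
                end = _pick_position(rng, sd, -contact + 0.5, contact - 0.5, margin=8.0)
                path = _walk_backward(rng, end, step_px, n_steps, (h, w), margin=8.0)
            else:  # extravasated
                end = _pick_position(rng, sd, -np.inf, -(contact + 1.0), margin=8.0)
                path = _walk_backward(rng, end, step_px, n_steps, (h, w), margin=8.0)
            arr = np.asarray(path)
            # non-crossing guarantee: stay separated from every placed
            # particle in every frame
            if all(
                float(np.min(np.linalg.norm(arr - other, axis=1)))
                >= motion.min_separation_px
                for other in placed_paths
            ):
                break
        else:
            raise ValueError(
                f"particle {i}: could not place a {fate!r} path at least "
                f"{motion.min_separation_px} px from the rest of the cohort"
            )
        placed_paths.append(arr)
        positions = [
            (k * motion.frame_interval_s, float(p[1]), float(p[0]))
            for k, p in enumerate(path)
        ]
        tracks.append(ParticleTrack(track_id=i, positions=positions, fate=fate))

    frames = np.full((motion.n_frames, h, w), motion.background_intensity, dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    for tr in tracks:
        for k, (_, x, y) in enumerate(tr.positions):
            frames[k] += motion.spot_amplitude * np.exp(
                -((yy - y) ** 2 + (xx - x) ** 2) / (2.0 * motion.spot_sigma_px**2)
            )
    if motion.noise_sigma > 0:
        frames = np.clip(
            frames + rng.normal(0.0, motion.noise_sigma, frames.shape), 0.0, None
        )
    stack = ImageStack(
        channels={"PMN": frames},
        pixel_size_um=px,
        frame_interval_s=motion.frame_interval_s,
    )
    truth.tracks = tracks
    truth.fates = list(motion.fates)
    return stack, tracks
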