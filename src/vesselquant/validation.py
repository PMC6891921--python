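"""Ground-truth recovery experiments against the phantom generator.

Each function runs one validation study end-to-end — generate phantoms
with known truth, run the measurement pipeline, score the recovery — and
returns a flat dict of summary numbers.  The numbered analysis drivers
and the acceptance script are thin wrappers over these.

All randomness is controlled by explicit seeds; sub-experiments derive
their seeds from a base seed so a single integer reproduces everything.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import f_oneway

from . import imgproc, morphometry, permeability, phantom, tracking
from .stack import ImageStack

__all__ = [
    "morphometry_recovery",
    "permeability_recovery",
    "null_permeability",
    "tracking_recovery",
    "imgproc_oracle_errors",
    "anova_type_one_error",
]

PMN_DETECT_THRESHOLD = 30.0
PMN_MAX_DISP_PX = 18.0
LEAKAGE_NOISE_FRACTION = 0.05  # of the vessel/tissue contrast


def _match_branches(graph: morphometry.SkeletonGraph, spec: phantom.PhantomSpec) -> list[int]:
    """Assign each skeleton branch to the truth branch it follows."""
    segs = [
        (np.asarray(b.points[0], float), np.asarray(b.points[-1], float))
        for b in spec.branches
    ]
    out = []
    for br in graph.branches:
        path = np.asarray(br.path, dtype=float)
        dists = []
        for a, b in segs:
            ab = b - a
            t = np.clip(((path - a) @ ab) / float(ab @ ab), 0.0, 1.0)
            dists.append(float(np.linalg.norm(path - (a + t[:, None] * ab), axis=1).mean()))
        out.append(int(np.argmin(dists)))
    return out


def morphometry_recovery(seed: int, n_phantoms: int = 10) -> dict:
    """Topology, coverage, length and diameter recovery on random trees."""
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_phantoms)
    topo_exact = 0
    coverage_exact = 0
    len_errs: list[float] = []
    diam_errs: list[float] = []
    for s in sub_seeds:
        spec = phantom.random_tree_network(int(s))
        _, truth = phantom.generate_network_phantom(spec)
        graph = morphometry.skeletonize(truth.mask)
        record = morphometry.morphometry_record(truth.mask, graph)
        ratio_truth = truth.connectivity_ratio
        if (
            graph.n_junctions == truth.n_junctions
            and graph.n_endpoints == truth.n_endpoints
            and record.connectivity_ratio == ratio_truth
        ):
            topo_exact += 1
        if record.coverage_pct == truth.area_fraction * 100.0:
            coverage_exact += 1
        idx = _match_branches(graph, spec)
        _, per_diam = morphometry.diameter_profile(truth.mask, graph)
        for br, dia, i in zip(graph.branches, per_diam, idx):
            t_len = spec.branches[i].length_px()
            t_dia = 2.0 * spec.branches[i].radius_px
            len_errs.append(abs(br.length_px - t_len) / t_len)
            diam_errs.append(abs(dia - t_dia) / t_dia)
    return {
        "n_phantoms": n_phantoms,
        "topology_exact_pct": 100.0 * topo_exact / n_phantoms,
        "coverage_exact_pct": 100.0 * coverage_exact / n_phantoms,
        "branch_length_max_rel_err_pct": 100.0 * float(np.max(len_errs)),
        "diameter_max_rel_err_pct": 100.0 * float(np.max(diam_errs)),
    }


def permeability_recovery(
    seed: int,
    P_grid=(1e-7, 1e-6, 1e-5),
    n_noise_seeds: int = 20,
) -> dict:
    """Forward-model inversion, noise-free and at 5% Gaussian noise."""
    spec = phantom.single_vessel_phantom(radius_px=10.0)
    _, truth = phantom.generate_network_phantom(spec)
    rng = np.random.default_rng(seed)
    noise_seeds = rng.integers(0, 2**31 - 1, size=n_noise_seeds)

    noise_free_errs = []
    noisy_errs = []
    for P_true in P_grid:
        leak = phantom.LeakageSpec(P_true_cm_per_s=P_true, n_frames=4)
        series = phantom.simulate_leakage_series(truth, leak)
        res = permeability.permeability_series(series, truth.mask)
        noise_free_errs.append(abs(res.P_cm_per_s - P_true) / P_true)
        sigma = LEAKAGE_NOISE_FRACTION * (leak.I_V0 - leak.I_T0)
        for s in noise_seeds:
            leak_n = phantom.LeakageSpec(
                P_true_cm_per_s=P_true, n_frames=4, noise_sigma=sigma, seed=int(s)
            )
            series_n = phantom.simulate_leakage_series(truth, leak_n)
            res_n = permeability.permeability_series(series_n, truth.mask)
            noisy_errs.append(abs(res_n.P_cm_per_s - P_true) / P_true)
    return {
        "noise_free_max_rel_err_pct": 100.0 * float(np.max(noise_free_errs)),
        "noisy_median_rel_err_pct": 100.0 * float(np.median(noisy_errs)),
        "n_seeds": n_noise_seeds,
    }


def null_permeability(seed: int, n_noise_seeds: int = 20) -> dict:
    """P_true = 0 with noise: the estimate must be statistically zero."""
    spec = phantom.single_vessel_phantom(radius_px=10.0)
    _, truth = phantom.generate_network_phantom(spec)
    rng = np.random.default_rng(seed)
    vals = []
    sigma = LEAKAGE_NOISE_FRACTION * (200.0 - 20.0)
    for s in rng.integers(0, 2**31 - 1, size=n_noise_seeds):
        leak = phantom.LeakageSpec(
            P_true_cm_per_s=0.0, n_frames=4, noise_sigma=sigma, seed=int(s)
        )
        series = phantom.simulate_leakage_series(truth, leak)
        vals.append(permeability.permeability_series(series, truth.mask).P_cm_per_s)
    mean = float(np.mean(vals))
    se = float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
    return {
        "mean_P_cm_per_s": mean,
        "se_P_cm_per_s": se,
        "abs_mean_over_se": abs(mean) / se if se > 0 else 0.0,
    }


def tracking_recovery(seed: int, n_cohorts: int = 5) -> dict:
    """Linking, speed and fate recovery on non-crossing PMN cohorts."""
    rng = np.random.default_rng(seed)
    n_tracks = 0
    n_linked = 0
    n_fates = 0
    speed_err_max = 0.0
    for s in rng.integers(0, 2**31 - 1, size=n_cohorts):
        series, truth, true_tracks = phantom.pmn_cohort_phantom(seed=int(s))
        frames = series.channel("PMN")
        dets = [tracking.detect_particles(f, PMN_DETECT_THRESHOLD) for f in frames]
        tracks = tracking.link_tracks(
            dets, max_disp_px=PMN_MAX_DISP_PX, frame_interval_s=series.frame_interval_s
        )
        n_tracks += len(true_tracks)
        for t in tracks:
            tt = min(
                true_tracks,
                key=lambda u: sum(
                    (a[1] - b[1]) ** 2 + (a[2] - b[2]) ** 2
                    for a, b in zip(t.positions, u.positions)
                ),
            )
            if t.n_frames == len(tt.positions) and all(
                np.hypot(a[1] - b[1], a[2] - b[2]) < 1.0
                for a, b in zip(t.positions, tt.positions)
            ):
                n_linked += 1
            if tracking.classify_track(t, truth.mask) == tt.fate:
                n_fates += 1
            # displacement-sum oracle on the measured positions
            pos = np.array([(x, y) for _, x, y in t.positions])
            elapsed_min = (t.positions[-1][0] - t.positions[0][0]) / 60.0
            oracle = float(
                np.sum(np.linalg.norm(np.diff(pos, axis=0), axis=1))
            ) / elapsed_min
            speed = tracking.mean_speed(t, truth.pixel_size_um)
            speed_err_max = max(speed_err_max, abs(speed - oracle))
    return {
        "n_tracks": n_tracks,
        "link_accuracy_pct": 100.0 * n_linked / n_tracks,
        "fate_accuracy_pct": 100.0 * n_fates / n_tracks,
        "speed_vs_oracle_max_abs_err": speed_err_max,
    }


def imgproc_oracle_errors(seed: int, size: int = 48) -> dict:
    """Brute-force oracle agreement for every preprocessing operator."""
    rng = np.random.default_rng(seed)
    from skimage.morphology import disk

    img = rng.uniform(0, 255, (size, size))

    # max projection vs per-pixel loop
    stack = np.stack([rng.uniform(0, 255, (size, size)) for _ in range(8)])
    proj = imgproc.max_project(ImageStack(channels={"EC": stack}), "EC")
    proj_err = float(np.max(np.abs(proj - stack.max(axis=0))))

    # outlier removal vs sliding-window median replacement
    radius, thresh = 2, 30.0
    out = imgproc.remove_outliers(img, radius, thresh)
    fp = disk(radius).astype(bool)
    pad = np.pad(img, radius, mode="symmetric")
    oracle = img.copy()
    for i in range(size):
        for j in range(size):
            win = pad[i : i + 2 * radius + 1, j : j + 2 * radius + 1][fp]
            med = float(np.median(win))
            if abs(img[i, j] - med) > thresh:
                oracle[i, j] = med
    median_err = float(np.max(np.abs(out - oracle)))

    # gaussian smoothing vs dense truncated-kernel convolution
    sigma = 2.0
    half = int(4 * sigma + 0.5)
    ax = np.arange(-half, half + 1)
    k1 = np.exp(-(ax**2) / (2 * sigma**2))
    k1 /= k1.sum()
    kernel = np.outer(k1, k1)
    padg = np.pad(img, half, mode="symmetric")
    dense = np.empty_like(img)
    for i in range(size):
        for j in range(size):
            dense[i, j] = np.sum(padg[i : i + 2 * half + 1, j : j + 2 * half + 1] * kernel)
    smooth = imgproc.gaussian_smooth(img, sigma)
    gauss_rel_err = float(np.max(np.abs(smooth - dense) / np.abs(dense)))

    # binarization vs explicit comparison with the realised threshold
    mask = imgproc.binarize(img, "otsu")
    bin_err = int(np.sum(mask.data != (img > mask.provenance["threshold"])))

    return {
        "max_project_max_abs_err": proj_err,
        "median_replacement_max_abs_err": median_err,
        "gaussian_max_rel_err": gauss_rel_err,
        "binarize_mismatched_px": bin_err,
    }


def anova_type_one_error(
    seed: int, n_replicates: int = 1000, k_groups: int = 3, n_per_group: int = 5
) -> dict:
    """One-way ANOVA rejection rate under a simulated global null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        groups = rng.normal(0.0, 1.0, (k_groups, n_per_group))
        _, p = f_oneway(*groups)
        rejections += p < 0.05
    return {
        "type_one_error": rejections / n_replicates,
        "n_replicates": n_replicates,
    }
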