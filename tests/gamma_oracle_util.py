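"""Shared helpers for gamma-index tests: smooth dose pairs and an
independent exhaustive brute-force oracle (dense lattice at half the
production search step, per-voxel full minimization)."""

import numpy as np
from scipy.ndimage import gaussian_filter


def smooth_pair(rng, shape=(24, 24), perturb=0.05):
    """A smooth reference dose (max 45 Gy) and a smoothly perturbed copy."""
    base = gaussian_filter(rng.random(shape), 3.0)
    truth = 45.0 * base / base.max()
    noise = gaussian_filter(rng.normal(size=shape), 2.0)
    pred = np.clip(truth + perturb * 45.0 * noise / np.abs(noise).max(), 0, None)
    return pred, truth


def bruteforce_pass_rate(pred, truth, params, spacing):
    """Exhaustive 2-D gamma pass rate, independent of the production path."""
    from scipy.interpolate import RegularGridInterpolator

    step = params.interp_step_mm / 2.0
    radius = params.search_radius_mm
    ax = np.arange(-radius, radius + step / 2, step)
    offs = np.stack(np.meshgrid(ax, ax, indexing="ij"), -1).reshape(-1, 2)
    offs = offs[np.linalg.norm(offs, axis=1) <= radius + 1e-9]
    geom = (np.linalg.norm(offs, axis=1) / params.dta_mm) ** 2

    ref_max = truth.max()
    delta_d = params.dose_tolerance_pct / 100.0 * ref_max
    evaluate = truth >= params.low_dose_threshold_pct_of_max / 100.0 * ref_max
    ys = np.arange(truth.shape[0]) * spacing[0]
    xs = np.arange(truth.shape[1]) * spacing[1]
    interp = RegularGridInterpolator((ys, xs), pred)

    passes, total = 0, 0
    for i, j in np.argwhere(evaluate):
        pts = np.array([i * spacing[0], j * spacing[1]]) + offs
        pts[:, 0] = np.clip(pts[:, 0], ys[0], ys[-1])   # edge clamp
        pts[:, 1] = np.clip(pts[:, 1], xs[0], xs[-1])
        dd = (interp(pts) - truth[i, j]) ** 2 / delta_d ** 2
        total += 1
        passes += (geom + dd).min() <= (1.0 + 1e-9) ** 2
    return passes / total * 100.0
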