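"""Multi-loss fusion for dose prediction: MSE, one-sided PTV voxel loss,
and an adjacent-pair rank loss, applied with deep supervision.

The fused objective is ``L = Lm + Lp + Lr`` per prediction branch:

* ``Lm`` — half mean squared error, ``(1/2m) * sum((p - y)^2)``.
* ``Lp`` — voxel loss splitting the grid by the PTV contour: inside the
  PTV every deviation is penalized (weight ``lambda_k = 0.7``); outside
  only over-dosing, i.e. ``max(p - y, 0)``, is penalized (weight
  ``mu_i = 0.3``) so predictions that fall off faster than the plan are
  never punished.
* ``Lr`` — a learning-to-rank term that sorts the target ascending,
  reorders the prediction by the same pixel permutation, and scores every
  adjacent pair with a logistic likelihood; it drives the *ordering* of
  predicted dose values toward the target's, the property DVH metrics
  (D98, D95, ...) measure.

Losses operate on the autodiff tensors used in training; plain arrays are
accepted and wrapped.  Deep supervision sums the fused loss over the four
pyramid levels against area-averaged downsampled targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .grids import PredictionPyramid

__all__ = [
    "LossConfig",
    "RankOrdering",
    "mse_loss",
    "voxel_loss",
    "rank_ordering",
    "rank_loss",
    "fused_loss",
    "deep_supervised_loss",
    "downsample_target",
    "downsample_mask",
]


@dataclass
class LossConfig:
    """Weights and variants of the fused loss.

    ``components`` selects the active terms and accepts the ablation names
    "Lm", "Lm&Lp", "Lm&Lp&Lr" via :meth:`from_string`.  ``rank_variant``
    chooses between the corrected pairwise log-likelihood ("log1m",
    default) and the literal printed form ("as_printed") in which the
    complement term is ``(1 - omega) * (1 - log rho)``.
    """

    lambda_k: float = 0.7
    mu_i: float = 0.3
    rank_variant: str = "log1m"
    components: tuple[str, ...] = ("Lm", "Lp", "Lr")
    branch_weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.lambda_k < 0 or self.mu_i < 0:
            raise ValueError("loss weights must be non-negative")
        if self.rank_variant not in ("log1m", "as_printed"):
            raise ValueError(f"unknown rank variant {self.rank_variant!r}")
        unknown = set(self.components) - {"Lm", "Lp", "Lr"}
        if unknown:
            raise ValueError(f"unknown loss components {unknown}")

    @classmethod
    def from_string(cls, spec: str, **kwargs) -> "LossConfig":
        return cls(components=tuple(spec.split("&")), **kwargs)


@dataclass
class RankOrdering:
    """Diagnostic view of the rank loss's sorting step (numpy only)."""

    lambda_index: np.ndarray   # permutation sorting the target ascending
    y_star: np.ndarray         # target, sorted
    p_star: np.ndarray         # prediction reordered by the same permutation
    rho: np.ndarray            # logistic score of adjacent prediction pairs
    omega: np.ndarray          # adjacent target-pair labels in {1, 1/2}


def _flat(x) -> ad.Tensor:
    t = ad.as_tensor(x)
    return ad.reshape(t, (-1,))


def mse_loss(p, y) -> ad.Tensor:
    """Half mean squared error, (1/2m) * ||p - y||^2."""
    p, y = _flat(p), _flat(y)
    if p.shape != y.shape:
        raise ValueError("prediction/target shape mismatch")
    d = p - y
    return ad.tsum(ad.mul(d, d)) * (0.5 / p.size)


def voxel_loss(p, y, ptv_mask, config: LossConfig | None = None) -> ad.Tensor:
    """PTV-region loss: symmetric inside the target, one-sided outside."""
    config = config or LossConfig()
    p, y = _flat(p), _flat(y)
    if p.shape != y.shape:
        raise ValueError("prediction/target shape mismatch")
    mask = np.asarray(ptv_mask).reshape(-1).astype(bool)
    if mask.shape != p.shape:
        raise ValueError("PTV mask shape mismatch")
    d = p - y
    dtype = d.dtype if np.issubdtype(d.dtype, np.floating) else np.float64
    n_in = int(mask.sum())
    n_out = int((~mask).sum())
    total = ad.Tensor(np.zeros((), dtype=dtype))
    if n_in:
        inside = ad.mul(d, mask.astype(dtype))
        total = total + ad.tsum(ad.mul(inside, inside)) * (config.lambda_k / (2.0 * n_in))
    if n_out:
        over = ad.relu(ad.mul(d, (~mask).astype(dtype)))
        total = total + ad.tsum(ad.mul(over, over)) * (config.mu_i / (2.0 * n_out))
    return total


def rank_ordering(p, y) -> RankOrdering:
    """Stable ascending sort of the target with the prediction reordered."""
    p = np.asarray(p if not isinstance(p, ad.Tensor) else p.data, dtype=float).reshape(-1)
    y = np.asarray(y if not isinstance(y, ad.Tensor) else y.data, dtype=float).reshape(-1)
    if p.shape != y.shape:
        raise ValueError("prediction/target shape mismatch")
    perm = np.argsort(y, kind="stable")
    y_star, p_star = y[perm], p[perm]
    dp = np.diff(p_star)
    rho = 1.0 / (1.0 + np.exp(-dp))
    dy = np.diff(y_star)
    omega = np.where(dy > 0, 1.0, 0.5)  # dy < 0 unreachable after ascending sort
    return RankOrdering(perm, y_star, p_star, rho, omega)


def rank_loss(p, y, config: LossConfig | None = None) -> ad.Tensor:
    """Adjacent-pair logistic rank loss on the target-sorted pixel order."""
    config = config or LossConfig()
    pt = _flat(p)
    y = np.asarray(y if not isinstance(y, ad.Tensor) else y.data, dtype=float).reshape(-1)
    m = pt.size
    if m != y.size:
        raise ValueError("prediction/target shape mismatch")
    if m < 2:
        raise ValueError("rank loss needs at least two pixels")
    perm = np.argsort(y, kind="stable")
    p_star = ad.take(pt, perm)
    d = p_star[1:] - p_star[:-1]
    dtype = d.dtype if np.issubdtype(d.dtype, np.floating) else np.float64
    omega = np.where(np.diff(y[perm]) > 0, 1.0, 0.5).astype(dtype)
    log_rho = -ad.softplus(-d)                      # log sigmoid(d), stable
    if config.rank_variant == "log1m":
        log_1m_rho = -ad.softplus(d)                # log sigmoid(-d)
        terms = ad.mul(log_rho, omega) + ad.mul(log_1m_rho, 1.0 - omega)
    else:  # literal printed form: (1 - omega) * (1 - log rho)
        terms = ad.mul(log_rho, omega) + ad.mul(1.0 - log_rho, 1.0 - omega)
    return ad.tsum(terms) * (-0.5 / m)


def fused_loss(p, y, ptv_mask, config: LossConfig | None = None) -> ad.Tensor:
    """Sum of the enabled components (Lm, Lp, Lr)."""
    config = config or LossConfig()
    terms = []
    if "Lm" in config.components:
        terms.append(mse_loss(p, y))
    if "Lp" in config.components:
        terms.append(voxel_loss(p, y, ptv_mask, config))
    if "Lr" in config.components:
        terms.append(rank_loss(p, y, config))
    if not terms:
        return ad.Tensor(np.zeros(()))
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total


def downsample_target(y: np.ndarray, factor: int) -> np.ndarray:
    """Area-average downsampling; preserves mean dose per region."""
    if factor == 1:
        return np.asarray(y, dtype=float)
    h, w = y.shape
    return np.asarray(y, dtype=float).reshape(h // factor, factor, w // factor, factor).mean(axis=(1, 3))


def downsample_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    """Majority-vote mask downsampling (area average thresholded at 1/2)."""
    return downsample_target(np.asarray(mask, dtype=float), factor) >= 0.5


def deep_supervised_loss(
    pyramid: PredictionPyramid,
    y: np.ndarray,
    ptv_mask: np.ndarray,
    config: LossConfig | None = None,
    targets: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> ad.Tensor:
    """Branch-weighted sum of fused losses over the four pyramid levels.

    ``targets`` may carry precomputed (target, ptv_mask) pairs per level,
    coarse to fine, to avoid re-downsampling every step.
    """
    config = config or LossConfig()
    if targets is None:
        targets = make_target_pyramid(y, ptv_mask)
    total = None
    for w, p_i, (y_i, m_i) in zip(config.branch_weights, pyramid.levels, targets):
        if w == 0:
            continue
        term = fused_loss(p_i, y_i, m_i, config) * float(w)
        total = term if total is None else total + term
    return total if total is not None else ad.Tensor(np.zeros(()))


def make_target_pyramid(y: np.ndarray, ptv_mask: np.ndarray):
    """Downsampled (target, mask) pairs at 1/8, 1/4, 1/2, 1/1 resolution."""
    return [
        (downsample_target(y, f), downsample_mask(ptv_mask, f))
        for f in (8, 4, 2, 1)
    ]
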