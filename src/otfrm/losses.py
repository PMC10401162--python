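"""Pretraining loss formulas: cross-entropy and the equalized focal loss.

The equalized focal loss (EFL) targets long-tailed multiclass problems.
Starting from the focal form ``−α_t (1 − p_t)^γ log p_t``, the focusing
factor for category j is decomposed as

    γ^j = γ_b + γ_v^j = γ_b + s (1 − g^j)

where ``γ_b`` controls the balanced-data behaviour, ``g^j ∈ [0, 1]``
measures how balanced category j is (1 = fully balanced), and ``s``
scales the extra focusing applied to imbalanced categories.  Each
category's contribution is further re-weighted by
``(γ_b + γ_v^j) / γ_b`` so rare categories (small g) count more while
balanced ones keep weight ≈ 1:

    EFL = −Σ_j α_t · (γ_b + γ_v^j)/γ_b · (1 − p_t^j)^{γ_b + γ_v^j} · log p_t^j

These are pure, testable formulas; no autodiff or training machinery is
attached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "EFLParams",
    "cross_entropy",
    "focusing_factor",
    "weighting_factor",
    "focal_loss",
    "equalized_focal_loss",
    "multitask_loss",
]

_CLAMP = 1e-12  # confidence floor before log


@dataclass(frozen=True)
class EFLParams:
    """Equalized-focal-loss hyperparameters.

    alpha_t: positive/negative balancing weight (default 1).
    gamma_b: basic focusing factor, > 0 (it divides the weighting factor).
    s: scale of the imbalance-driven variable factor, ≥ 0.
    g: per-category balance values in [0, 1]; g=1 means balanced.
    """

    alpha_t: float = 1.0
    gamma_b: float = 2.0
    s: float = 0.0
    g: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gamma_b <= 0:
            raise ValueError(f"gamma_b must be > 0, got {self.gamma_b}")
        if self.s < 0:
            raise ValueError(f"s must be ≥ 0, got {self.s}")
        for j, gj in self.g.items():
            if not (0.0 <= gj <= 1.0):
                raise ValueError(f"g[{j!r}] = {gj} outside [0, 1]")


def cross_entropy(p: Sequence[float], q: Sequence[float]) -> float:
    """Multiclass cross-entropy ``−Σ_i p_i log q_i``.

    ``p`` is the true (one-hot or simplex) distribution, ``q`` the
    prediction; q is clamped at 1e−12 before the log.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {q.shape}")
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("p must lie in the probability simplex")
    if np.any(q < 0):
        raise ValueError("q must be nonnegative")
    return float(-np.sum(p * np.log(np.clip(q, _CLAMP, None))))


def focusing_factor(j: str, params: EFLParams) -> float:
    """Category focusing factor ``γ^j = γ_b + s (1 − g_j)``."""
    if j not in params.g:
        raise KeyError(f"unknown category {j!r}")
    return params.gamma_b + params.s * (1.0 - params.g[j])


def weighting_factor(j: str, params: EFLParams) -> float:
    """Category re-weighting ``(γ_b + γ_v^j) / γ_b`` = γ^j / γ_b."""
    return focusing_factor(j, params) / params.gamma_b


def focal_loss(p_t: float, alpha_t: float = 1.0, gamma: float = 2.0) -> float:
    """Plain focal term ``−α_t (1 − p_t)^γ log p_t`` for one target."""
    if not (0.0 < p_t <= 1.0):
        raise ValueError(f"p_t must lie in (0, 1], got {p_t}")
    return -alpha_t * (1.0 - p_t) ** gamma * math.log(max(p_t, _CLAMP))


def equalized_focal_loss(p_t: Mapping[str, float], params: EFLParams) -> float:
    """Equalized focal loss over the given per-category confidences."""
    total = 0.0
    for j, pj in p_t.items():
        if not (0.0 < pj <= 1.0):
            raise ValueError(f"p_t[{j!r}] = {pj} outside (0, 1]")
        gamma_j = focusing_factor(j, params)
        total += (
            -params.alpha_t
            * (gamma_j / params.gamma_b)
            * (1.0 - pj) ** gamma_j
            * math.log(max(pj, _CLAMP))
        )
    return total


def multitask_loss(
    ce: float, efl: float, w_ce: float = 1.0, w_efl: float = 1.0
) -> float:
    """Weighted sum of a cross-entropy term and an EFL term (the
    combined pretraining objective); unit weights by default."""
    return w_ce * ce + w_efl * efl
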