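"""The OTFRM score and the analyses built on it.

For a feature space of K tasks the OTFRM of task k is

    OTFRM(k) = intra_sim(k) / inter_sim(k)

with

    intra_sim(k) = (2 / (m_k (m_k − 1))) Σ_{i<j} cos(x_i, x_j)
    inter_sim(k) = (1 / (K − 1)) Σ_{l ≠ k} OTsim(C_k, C_l)

where OTsim is ``1 − W_p`` under the cosine ground cost (see
:mod:`otfrm.ot`).  Both components lie in [−1, 1]; a larger OTFRM means
a tighter task cluster that is better separated from the other tasks.
Tracking the score across training stages (randomly initialized →
pretrained → fine-tuned) quantifies how much each task's feature-space
organization benefits from each stage; the K×K matrix of pairwise
W_p distances predicts task-to-task adaptability (closer tasks transfer
better), which also yields a source-task ranking for transfer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .exceptions import IllConditionedRatioError, UndefinedStatisticError
from .ot import OTConfig, ot_similarity, wasserstein_p
from .store import FeatureSpace, TaskEmbeddingSet

__all__ = [
    "OTFRMReport",
    "StageComparison",
    "intra_task_similarity",
    "inter_task_similarity",
    "otfrm_score",
    "otfrm_report",
    "pairwise_distance_matrix",
    "stage_comparison",
    "spearman_rho",
    "adaptability_correlation",
    "rank_transfer_sources",
]

#: below this, the inter-task similarity denominator is treated as
#: ill-conditioned and the ratio is refused rather than reported as ±inf
RATIO_GUARD = 1e-8

_STAGE_KEYS = ("randomly_initialized", "pretrained", "fine_tuned")


def intra_task_similarity(task: TaskEmbeddingSet | np.ndarray) -> float:
    """Mean cosine similarity over all unique sample pairs of one task."""
    X = task.embeddings if isinstance(task, TaskEmbeddingSet) else np.asarray(task)
    m = X.shape[0]
    if m < 2:
        raise UndefinedStatisticError(
            f"intra-task similarity needs m ≥ 2 samples, got {m}"
        )
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms < 1e-12):
        raise UndefinedStatisticError("zero-norm vector: cosine similarity undefined")
    U = X / norms[:, None]
    G = np.clip(U @ U.T, -1.0, 1.0)
    iu = np.triu_indices(m, k=1)
    return float(G[iu].mean())


def inter_task_similarity(
    task_id: str, fs: FeatureSpace, cfg: OTConfig | None = None
) -> float:
    """Mean OT similarity between one task and every other task."""
    cfg = cfg or OTConfig()
    if fs.K < 2:
        raise UndefinedStatisticError("inter-task similarity needs K ≥ 2 tasks")
    ref = fs[task_id]
    sims = [
        ot_similarity(ref.embeddings, other.embeddings, cfg)
        for other in fs
        if other.task_id != task_id
    ]
    return float(np.mean(sims))


def otfrm_score(
    task_id: str,
    fs: FeatureSpace,
    cfg: OTConfig | None = None,
    guard: float = RATIO_GUARD,
) -> float:
    """The OTFRM of one task: intra-task / inter-task similarity."""
    intra = intra_task_similarity(fs[task_id])
    inter = inter_task_similarity(task_id, fs, cfg)
    if inter <= guard:
        raise IllConditionedRatioError(
            f"inter-task similarity {inter:.3e} ≤ guard {guard:.0e} for task "
            f"{task_id!r}; the OTFRM ratio is undefined here",
            numerator=intra,
            denominator=inter,
        )
    return intra / inter


@dataclass
class OTFRMReport:
    """Per-task OTFRM components plus the pairwise W_p distance matrix."""

    per_task: dict[str, dict[str, float]]
    pairwise_distance: np.ndarray
    task_ids: list[str]
    config: OTConfig

    def to_dict(self) -> dict:
        return {
            "per_task": self.per_task,
            "task_ids": self.task_ids,
            "pairwise_distance": self.pairwise_distance.tolist(),
            "config": {
                "p": self.config.p,
                "epsilon": self.config.epsilon,
                "solver": self.config.solver,
                "max_iter": self.config.max_iter,
                "marginal_tol": self.config.marginal_tol,
                "subsample_cap": self.config.subsample_cap,
                "subsample_seed": self.config.subsample_seed,
            },
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def pairwise_distance_matrix(fs: FeatureSpace, cfg: OTConfig | None = None) -> np.ndarray:
    """K×K matrix of p-Wasserstein distances between task distributions.

    Symmetric by construction (each unordered pair is solved once); the
    diagonal is exactly zero under the exact solver and near zero, up to
    the entropic bias, under Sinkhorn.
    """
    cfg = cfg or OTConfig()
    if fs.K < 2:
        raise UndefinedStatisticError("pairwise distances need K ≥ 2 tasks")
    K = fs.K
    D = np.zeros((K, K))
    for k in range(K):
        D[k, k] = wasserstein_p(fs.tasks[k].embeddings, fs.tasks[k].embeddings, cfg)
        for l in range(k + 1, K):
            D[k, l] = D[l, k] = wasserstein_p(
                fs.tasks[k].embeddings, fs.tasks[l].embeddings, cfg
            )
    if cfg.solver == "exact":
        np.fill_diagonal(D, 0.0)
    return D


def otfrm_report(fs: FeatureSpace, cfg: OTConfig | None = None) -> OTFRMReport:
    """Score every task of a feature space and collect the distances.

    OT similarities are derived from the same pairwise distance matrix
    used for the adaptability analysis, so the two views are consistent.
    """
    cfg = cfg or OTConfig()
    D = pairwise_distance_matrix(fs, cfg)
    S = 1.0 - D  # OT similarity
    per_task: dict[str, dict[str, float]] = {}
    for k, task in enumerate(fs):
        intra = intra_task_similarity(task)
        inter = float(np.mean(np.delete(S[k], k)))
        entry: dict[str, float] = {"intra_sim": intra, "inter_sim": inter}
        if inter > RATIO_GUARD:
            entry["otfrm"] = intra / inter
        else:
            entry["otfrm"] = float("nan")
        per_task[task.task_id] = entry
    return OTFRMReport(
        per_task=per_task, pairwise_distance=D, task_ids=fs.task_ids, config=cfg
    )


@dataclass
class StageComparison:
    """Per-task OTFRM at each training stage, with stage-over-stage ratios.

    ``ratio_PT_over_RI`` and ``ratio_FT_over_PT`` are ``None`` when the
    denominator stage's OTFRM does not exceed the positivity guard.
    """

    per_task: dict[str, dict[str, float | None]] = field(default_factory=dict)


def stage_comparison(
    snapshots: dict[str, FeatureSpace],
    cfg: OTConfig | None = None,
    guard: float = RATIO_GUARD,
) -> StageComparison:
    """Compare OTFRM across the three training-stage snapshots.

    ``snapshots`` must map each of ``randomly_initialized``,
    ``pretrained`` and ``fine_tuned`` to a FeatureSpace over the same
    task_ids.
    """
    cfg = cfg or OTConfig()
    missing = [s for s in _STAGE_KEYS if s not in snapshots]
    if missing:
        raise ValueError(f"missing stage snapshot(s): {missing}")
    id_sets = {s: set(snapshots[s].task_ids) for s in _STAGE_KEYS}
    if not (id_sets["randomly_initialized"] == id_sets["pretrained"] == id_sets["fine_tuned"]):
        raise ValueError(f"stage snapshots disagree on task_ids: {id_sets}")

    scores = {
        s: {tid: otfrm_score(tid, snapshots[s], cfg) for tid in snapshots[s].task_ids}
        for s in _STAGE_KEYS
    }
    comparison = StageComparison()
    for tid in snapshots["randomly_initialized"].task_ids:
        ri = scores["randomly_initialized"][tid]
        pt = scores["pretrained"][tid]
        ft = scores["fine_tuned"][tid]
        comparison.per_task[tid] = {
            "otfrm_RI": ri,
            "otfrm_PT": pt,
            "otfrm_FT": ft,
            "ratio_PT_over_RI": pt / ri if ri > guard else None,
            "ratio_FT_over_PT": ft / pt if pt > guard else None,
        }
    return comparison


def _average_ranks(x: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties receiving the average of their positions."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=np.float64)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: average-rank transform, then the
    Pearson product-moment formula on the ranks."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if len(x) < 3:
        raise UndefinedStatisticError("rank correlation needs n ≥ 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedStatisticError("constant vector: correlation undefined")
    rx = _average_ranks(x) - _average_ranks(x).mean()
    ry = _average_ranks(y) - _average_ranks(y).mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def adaptability_correlation(distances, deltas) -> tuple[float, int]:
    """Rank correlation between pairwise task distances and the observed
    adaptation performance changes; a negative rho supports "farther
    apart transfers worse".  Returns ``(rho, n)``."""
    distances = np.asarray(distances, dtype=np.float64)
    deltas = np.asarray(deltas, dtype=np.float64)
    return spearman_rho(distances, deltas), len(distances)


def rank_transfer_sources(
    target: str, fs: FeatureSpace, cfg: OTConfig | None = None
) -> list[str]:
    """Rank candidate source tasks for transfer to ``target``.

    Closest-first by W_p distance (the empirically best-adapting sources
    are the nearest ones); ties broken lexicographically by task_id.
    """
    cfg = cfg or OTConfig()
    if target not in fs:
        raise KeyError(f"unknown target task {target!r}")
    if fs.K < 2:
        raise UndefinedStatisticError("source ranking needs K ≥ 2 tasks")
    tgt = fs[target]
    dist = {
        t.task_id: wasserstein_p(tgt.embeddings, t.embeddings, cfg)
        for t in fs
        if t.task_id != target
    }
    return sorted(dist, key=lambda tid: (dist[tid], tid))
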