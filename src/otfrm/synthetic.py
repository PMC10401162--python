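"""Seeded synthetic data: feature spaces, stage snapshots, annotation
corpora and adaptation outcomes.

Feature spaces are drawn as K isotropic Gaussian clusters in dimension
d, one cluster per task.  Cluster means sit on a sphere around a shared
nonzero centroid and are placed at *exact* pairwise distance
``delta · sigma`` from each other (Gram–Schmidt construction, available
whenever K + 1 ≤ d).  ``delta`` is therefore a single knob for
between-task separation in units of the within-task standard deviation:
``delta = 0`` reproduces the fully mixed picture of untrained
representations, large ``delta`` the tight, well-separated clusters of
fine-tuned ones.  The shared centroid (norm ``center_norm · sigma``)
reflects the positive mean pairwise cosine similarity real embedding
spaces exhibit; without it, cosine statistics at ``delta = 0`` would
fluctuate around zero and ratio-based scores would be sign-unstable for
reasons that have nothing to do with the metric.

Stage snapshots share cluster directions and per-sample noise across
stages, so increasing ``delta`` is the only difference between the
randomly-initialized, pretrained and fine-tuned spaces.

All generators draw from named, seed-derived streams: adding one
generator never shifts another's stream, and identical (spec, seed)
always reproduces identical output bitwise.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .bioes import KINDS, AnnotatedSequence, Span
from .exceptions import GenerationError
from .store import FeatureSpace, TaskEmbeddingSet

__all__ = [
    "SyntheticSpaceSpec",
    "generate_feature_space",
    "generate_stage_snapshots",
    "generate_annotated_corpus",
    "simulate_adaptation_outcomes",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: norm of the shared cluster centroid, in units of sigma
CENTER_NORM = 2.0


def _stream(seed: int, name: str) -> np.random.Generator:
    """A named child stream of ``seed``: independent per name, stable
    across the addition of new generators."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


@dataclass(frozen=True)
class SyntheticSpaceSpec:
    """Parameters of a synthetic K-task Gaussian feature space.

    delta is the exact pairwise distance between cluster means in units
    of sigma (the isotropic within-task standard deviation).
    """

    K: int = 6
    m: int = 50
    d: int = 16
    delta: float = 1.0
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be ≥ 1")
        if self.m < 2:
            raise ValueError("m must be ≥ 2")
        if self.d < 2:
            raise ValueError("d must be ≥ 2")
        if self.delta < 0:
            raise ValueError("delta must be ≥ 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def _cluster_geometry(
    spec: SyntheticSpaceSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Draw (centroid, unit mean directions, per-task noise) once.

    The K mean directions are mutually orthonormal and orthogonal to the
    centroid direction when K + 1 ≤ d (QR of a Gaussian matrix), so
    scaling them by delta·sigma/√2 puts every pair of means at exact
    distance delta·sigma.  For K + 1 > d the directions are plain unit
    vectors and separations are only approximate.
    """
    G = rng.standard_normal((spec.d, spec.K + 1))
    if spec.K + 1 <= spec.d:
        Q, R = np.linalg.qr(G)
        Q = Q * np.sign(np.diag(R))  # sign-fix for determinism
        center_dir, dirs = Q[:, 0], Q[:, 1:].T
    else:
        center_dir = G[:, 0] / np.linalg.norm(G[:, 0])
        dirs = (G[:, 1:] / np.linalg.norm(G[:, 1:], axis=0)).T
    center = CENTER_NORM * spec.sigma * center_dir
    noise = [rng.standard_normal((spec.m, spec.d)) for _ in range(spec.K)]
    return center, dirs, noise


def _assemble(
    spec: SyntheticSpaceSpec,
    delta: float,
    center: np.ndarray,
    dirs: np.ndarray,
    noise: list[np.ndarray],
    stage: str,
    rng: np.random.Generator,
) -> FeatureSpace:
    scale = delta * spec.sigma / np.sqrt(2.0)
    tasks = []
    for k in range(spec.K):
        mean = center + scale * dirs[k]
        X = mean[None, :] + spec.sigma * noise[k]
        # resample the (measure-zero) zero-norm rows so cosine is defined
        norms = np.linalg.norm(X, axis=1)
        while np.any(norms < 1e-9):
            bad = norms < 1e-9
            X[bad] = mean[None, :] + spec.sigma * rng.standard_normal(
                (int(bad.sum()), spec.d)
            )
            norms = np.linalg.norm(X, axis=1)
        tasks.append(
            TaskEmbeddingSet(task_id=f"task{k + 1}", embeddings=X, stage=stage)
        )
    return FeatureSpace(tasks)


def generate_feature_space(
    spec: SyntheticSpaceSpec, stage: str = "unspecified"
) -> FeatureSpace:
    """Draw one synthetic feature space from the spec."""
    rng = _stream(spec.seed, "feature_space")
    center, dirs, noise = _cluster_geometry(spec, rng)
    return _assemble(spec, spec.delta, center, dirs, noise, stage, rng)


def generate_stage_snapshots(
    spec: SyntheticSpaceSpec, deltas: tuple[float, float, float] = (0.0, 1.0, 4.0)
) -> dict[str, FeatureSpace]:
    """Three stage snapshots with ascending separation.

    Returns ``{"randomly_initialized": ..., "pretrained": ...,
    "fine_tuned": ...}`` over identical task_ids; cluster directions and
    sample noise are shared across stages, so the separations in
    ``deltas`` are the only difference between them.
    """
    if len(deltas) != 3 or not (deltas[0] <= deltas[1] <= deltas[2]):
        raise ValueError(f"deltas must be three ascending separations, got {deltas}")
    rng = _stream(spec.seed, "stage_snapshots")
    center, dirs, noise = _cluster_geometry(spec, rng)
    stages = ("randomly_initialized", "pretrained", "fine_tuned")
    return {
        stage: _assemble(spec, delta, center, dirs, noise, stage, rng)
        for stage, delta in zip(stages, deltas)
    }


def generate_annotated_corpus(
    n_sequences: int,
    length_range: tuple[int, int] = (50, 200),
    zipf_exponent: float = 2.0,
    n_categories: int = 20,
    seed: int = 0,
    max_entities_per_kind: int = 3,
    span_length_range: tuple[int, int] = (1, 12),
) -> tuple[list[AnnotatedSequence], dict[str, int]]:
    """A corpus of random amino-acid sequences with long-tailed span
    annotations.

    Per sequence and annotation kind, up to ``max_entities_per_kind``
    non-overlapping spans are placed; each span's category index is
    drawn from a Zipf law ``P(k) ∝ k^{−zipf_exponent}`` over
    ``n_categories`` kind-qualified categories (``Motif1`` the head,
    ``Motif<n>`` the tail).  Returns the sequences and the category
    occurrence counts (the input to :func:`otfrm.bioes.merge_long_tail`).
    """
    if zipf_exponent <= 1:
        raise ValueError("zipf_exponent must be > 1")
    if n_categories < 1 or n_sequences < 1:
        raise ValueError("need n_sequences ≥ 1 and n_categories ≥ 1")
    lo, hi = length_range
    if not (1 <= lo <= hi):
        raise GenerationError(f"infeasible length_range {length_range}")
    slo, shi = span_length_range
    if not (1 <= slo <= shi) or slo > hi:
        raise GenerationError(f"infeasible span_length_range {span_length_range}")

    rng = _stream(seed, "annotated_corpus")
    ranks = np.arange(1, n_categories + 1, dtype=np.float64)
    probs = ranks**-zipf_exponent
    probs /= probs.sum()

    sequences: list[AnnotatedSequence] = []
    counts: dict[str, int] = {}
    for s in range(n_sequences):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
        entities: list[Span] = []
        for kind in KINDS:
            occupied: list[tuple[int, int]] = []
            n_spans = int(rng.integers(0, max_entities_per_kind + 1))
            for _ in range(n_spans):
                placed = False
                for _attempt in range(20):
                    span_len = int(rng.integers(slo, min(shi, length) + 1))
                    start = int(rng.integers(1, length - span_len + 2))
                    end = start + span_len - 1
                    if all(end < a or start > b for a, b in occupied):
                        occupied.append((start, end))
                        cat_idx = int(rng.choice(n_categories, p=probs)) + 1
                        category = f"{kind.capitalize()}{cat_idx}"
                        entities.append(Span(start, end, category, kind))
                        counts[category] = counts.get(category, 0) + 1
                        placed = True
                        break
                if not placed:
                    break  # sequence too crowded; accept fewer spans
        sequences.append(
            AnnotatedSequence(sequence=seq, entities=entities, sequence_id=f"seq{s + 1}")
        )
    return sequences, counts


def simulate_adaptation_outcomes(
    distances, slope: float, noise_sd: float, seed: int = 0
) -> np.ndarray:
    """Simulated adaptation performance changes for given task distances.

    ``delta_i = slope · distance_i + N(0, noise_sd²)`` — a negative
    slope encodes "farther apart transfers worse", the relationship the
    adaptability correlation is designed to detect.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be ≥ 0")
    distances = np.asarray(distances, dtype=np.float64)
    rng = _stream(seed, "adaptation_outcomes")
    return slope * distances + noise_sd * rng.standard_normal(distances.shape)
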