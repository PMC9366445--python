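"""Pairwise image contrasts: the training material of the embedded
group-contrast protocol.

Instead of learning classes from single labelled images, the network is
trained on pairs of specimen images labelled same-group / different-group,
so even a few hundred specimens yield >10^5 training comparisons.  This
module enumerates those pairs, computes Euclidean image distances and
difference images, and lays out seeded, optionally class-balanced batch
streams for training rounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ImageContrast",
    "BatchPlan",
    "enumerate_contrasts",
    "image_distance",
    "difference_image",
    "render_difference",
    "plan_batches",
    "n_pairs",
]


@dataclass(slots=True)
class ImageContrast:
    id_a: str
    id_b: str
    same_group: bool
    distance: float | None = None


@dataclass(frozen=True)
class BatchPlan:
    """Layout of one training run's batch stream.

    ``pairs_per_round``: if set, each round draws that many contrasts
    (seeded; class-balanced when ``balanced``) instead of using the full
    list.  With the default (all pairs, unbalanced) every contrast appears
    exactly once per round.
    """

    batch_size: int = 64
    n_rounds: int = 10
    shuffle_seed: int = 0
    pairs_per_round: int | None = None
    balanced: bool = False


def n_pairs(n: int, ordered: bool = False) -> int:
    return n * (n - 1) if ordered else n * (n - 1) // 2


def enumerate_contrasts(manifest: pd.DataFrame, ordered: bool = False) -> list[ImageContrast]:
    """All pairwise contrasts of a manifest (``specimen_id``, ``group``).

    Ordered mode yields the n(n-1) directed pairs the source publications
    count; the default is the n(n-1)/2 unordered pairs (the contrastive loss
    is symmetric).
    """
    ids = manifest["specimen_id"].tolist()
    groups = manifest["group"].tolist()
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate specimen ids in manifest: {dupes[:5]}")
    if len(ids) < 2:
        raise ValueError("need at least 2 specimens to form contrasts")

    out: list[ImageContrast] = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            same = groups[i] == groups[j]
            out.append(ImageContrast(ids[i], ids[j], same))
            if ordered:
                out.append(ImageContrast(ids[j], ids[i], same))
    return out


def image_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean norm of the flattened pixel-wise difference (the image
    distance d of the contrast protocol)."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm((a - b).ravel()))


def difference_image(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-pixel absolute difference |a - b|."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return np.abs(a - b)


def render_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Difference image rendered for export: larger difference -> darker."""
    return 1.0 - difference_image(a, b)


def plan_batches(contrasts: Sequence[ImageContrast], plan: BatchPlan) -> list[list[np.ndarray]]:
    """Cut the contrast list into seeded per-round batch sequences.

    Each round is an independent permutation (the presentation order is
    reshuffled between rounds); the final batch of a round may be short.
    Returns ``rounds[r][b]`` = array of contrast indices.
    """
    if plan.batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    if len(contrasts) == 0:
        raise ValueError("contrast list is empty")

    same_idx = np.array([i for i, c in enumerate(contrasts) if c.same_group])
    diff_idx = np.array([i for i, c in enumerate(contrasts) if not c.same_group])
    rng = np.random.default_rng(plan.shuffle_seed)

    rounds = []
    for _ in range(plan.n_rounds):
        if plan.pairs_per_round is None:
            order = rng.permutation(len(contrasts))
        else:
            k = plan.pairs_per_round
            if plan.balanced and len(same_idx) and len(diff_idx):
                k_same = k // 2
                pick = np.concatenate([
                    rng.choice(same_idx, k_same, replace=len(same_idx) < k_same),
                    rng.choice(diff_idx, k - k_same, replace=len(diff_idx) < k - k_same),
                ])
            else:
                pick = rng.choice(len(contrasts), k, replace=len(contrasts) < k)
            order = rng.permutation(pick)
        rounds.append([order[i:i + plan.batch_size]
                       for i in range(0, len(order), plan.batch_size)])
    return rounds


def total_presentations(rounds: list[list[np.ndarray]]) -> int:
    return int(sum(len(b) for r in rounds for b in r))
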