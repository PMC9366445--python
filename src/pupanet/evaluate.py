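"""Identification scoring: confusion matrices, multiclass MCC, post-hoc
training-set identification, and the sequester-and-retrain jackknife.

The Matthews correlation coefficient is used as the headline accuracy
index because raw accuracy is biased when group sizes are unequal; the
multiclass (covariance / Gorodkin) form reduces to the classic binary
formula on 2x2 tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .network import TrainConfig, TrainedModel, classify_nearest_centroid, embed_set, train
from .synthetic import SpecimenImage

__all__ = ["ConfusionMatrix", "JackknifeReport", "mcc", "post_hoc_identify", "jackknife"]


@dataclass
class ConfusionMatrix:
    """g x g count table; rows = true group, columns = assigned group."""

    labels: list[str]
    counts: np.ndarray

    @classmethod
    def from_assignments(cls, true, pred, labels=None) -> "ConfusionMatrix":
        true, pred = np.asarray(true), np.asarray(pred)
        if labels is None:
            labels = sorted(set(true) | set(pred))
        labels = list(labels)
        index = {g: i for i, g in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for t, p in zip(true, pred):
            counts[index[t], index[p]] += 1
        return cls(labels, counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.n)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


def mcc(cm: ConfusionMatrix) -> float:
    """Multiclass Matthews correlation coefficient (covariance form).

    Returns 0 with a warning when a marginal is degenerate (e.g. all
    predictions in one class), the conventional value for an undefined
    denominator.
    """
    c = np.asarray(cm.counts, dtype=float)
    n = c.sum()
    if c.size == 0 or n < 1:
        raise ValueError("empty confusion matrix")
    t = c.sum(axis=1)  # true (row) marginals
    p = c.sum(axis=0)  # predicted (column) marginals
    cov_xy = n * np.trace(c) - t @ p
    cov_xx = n * n - p @ p
    cov_yy = n * n - t @ t
    if cov_xx <= 0 or cov_yy <= 0:
        warnings.warn("degenerate confusion-matrix marginal; MCC set to 0")
        return 0.0
    return float(cov_xy / np.sqrt(cov_xx * cov_yy))


def post_hoc_identify(model: TrainedModel, images: list[SpecimenImage],
                      manifest: pd.DataFrame):
    """Identify the raw training-set images with the trained system.

    Embeds all images, fits group centroids, classifies every image by
    nearest centroid, and tabulates.  Returns (ConfusionMatrix, accuracy,
    MCC).
    """
    ids = [im.specimen_id for im in images]
    if set(ids) != set(manifest["specimen_id"]):
        raise ValueError("manifest does not match the provided images")
    if manifest["group"].nunique() < 2:
        raise ValueError("post-hoc identification needs >= 2 groups")
    space = embed_set(model, images)
    assigned = classify_nearest_centroid(space, space.score_matrix())
    cm = ConfusionMatrix.from_assignments(space.scores["group"], assigned["group"],
                                          labels=sorted(set(space.scores["group"])))
    return cm, cm.accuracy(), mcc(cm)


@dataclass
class JackknifeReport:
    holdout_ids: list[str]
    records: pd.DataFrame          # specimen_id, true_group, assigned_group, group_missing
    confusion: ConfusionMatrix | None
    accuracy: float | None
    mcc: float | None
    seed: int


def jackknife(images: list[SpecimenImage], manifest: pd.DataFrame,
              n_holdout: int, config: TrainConfig, seed: int = 0) -> JackknifeReport:
    """Sequester-and-retrain cross-tabulation validation.

    ``n_holdout`` specimens are drawn at random (seeded); for each, the
    network is retrained from scratch on the remaining specimens and the
    holdout is classified by nearest centroid in the fresh feature space.
    Iterations whose holdout empties its group in the training set are
    flagged (the holdout is then scored against the remaining centroids).
    """
    n = len(images)
    if n_holdout >= n:
        raise ValueError("n_holdout must be smaller than the sample size")
    if n_holdout == 0:
        return JackknifeReport([], pd.DataFrame(
            columns=["specimen_id", "true_group", "assigned_group", "group_missing"]),
            None, None, None, seed)

    rng = np.random.default_rng(seed)
    order = rng.choice(n, size=n_holdout, replace=False)
    by_id = {im.specimen_id: im for im in images}
    holdout_ids = [images[i].specimen_id for i in order]

    rows = []
    for it, hid in enumerate(holdout_ids):
        keep = manifest["specimen_id"] != hid
        sub_manifest = manifest[keep].reset_index(drop=True)
        sub_images = [by_id[s] for s in sub_manifest["specimen_id"]]
        assert hid not in set(sub_manifest["specimen_id"])

        cfg = replace(config, init_seed=config.init_seed + it,
                      shuffle_seed=config.shuffle_seed + it)
        model = train(sub_images, sub_manifest, cfg)
        space = embed_set(model, sub_images)
        query = embed_set(model, [by_id[hid]]).score_matrix()
        assigned = classify_nearest_centroid(space, query)["group"].iloc[0]

        true_group = manifest.loc[manifest["specimen_id"] == hid, "group"].iloc[0]
        missing = true_group not in set(sub_manifest["group"])
        rows.append({"specimen_id": hid, "true_group": true_group,
                     "assigned_group": assigned, "group_missing": missing})

    records = pd.DataFrame(rows)
    cm = ConfusionMatrix.from_assignments(
        records["true_group"], records["assigned_group"],
        labels=sorted(set(records["true_group"]) | set(records["assigned_group"])))
    return JackknifeReport(holdout_ids, records, cm, cm.accuracy(), mcc(cm), seed)
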