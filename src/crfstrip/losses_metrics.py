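"""Training losses and evaluation metrics for binary segmentation.

Training uses a soft (probabilistic) Dice loss.  The composite loss adds a
*negative* Dice term between the pre-CRF prediction ``z`` and the post-CRF
prediction ``y``::

    L = D(y, y_true) - lambda * D(z, y)

which rewards the CRF layer for changing the base model's output by a
meaningful amount while the primary term anchors the refined prediction to
the ground truth.

Evaluation metrics (Dice coefficient, Jaccard index, Hausdorff distance)
operate on hard binary masks in canonical 1 mm space, so voxel units equal
millimetres.  The Hausdorff distance is the maximum of the two directed
distances (not a percentile variant).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import directed_hausdorff

from .autodiff import Tensor

__all__ = [
    "LossConfig", "MetricReport", "soft_dice_loss", "composite_loss",
    "dice_coefficient", "jaccard_index", "hausdorff_distance",
    "evaluate_pair", "write_metrics_csv",
]


@dataclass(frozen=True)
class LossConfig:
    """`lam` is the weight of the negative-Dice CRF regularizer (lambda)."""

    lam: float = 0.1
    epsilon: float = 1e-7

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


def soft_dice_loss(pred, truth, epsilon: float = 1e-7):
    """1 - (2 sum(p t) + eps) / (sum p + sum t + eps).

    Differentiable when given Tensors; also accepts plain arrays (returns a
    Tensor either way for uniformity).
    """
    p = pred if isinstance(pred, Tensor) else Tensor(np.asarray(pred, float))
    t = truth if isinstance(truth, Tensor) else Tensor(np.asarray(truth, float))
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    num = (p * t).sum() * 2.0 + epsilon
    den = p.sum() + t.sum() + epsilon
    return 1.0 - num / den


def composite_loss(y, y_true, z, cfg: LossConfig = LossConfig()):
    """D(y, y_true) - lambda * D(z, y); gradients flow through both terms."""
    return soft_dice_loss(y, y_true, cfg.epsilon) - \
        cfg.lam * soft_dice_loss(z, y, cfg.epsilon)


def _as_binary(a) -> np.ndarray:
    arr = np.asarray(a)
    return arr.astype(bool)


def dice_coefficient(a, b) -> float:
    """2|A n B| / (|A| + |B|) for binary masks."""
    a, b = _as_binary(a), _as_binary(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        warnings.warn("both masks empty; Dice defined as 1", stacklevel=2)
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def jaccard_index(a, b) -> float:
    """|A n B| / |A u B| for binary masks."""
    a, b = _as_binary(a), _as_binary(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    union = int((a | b).sum())
    if union == 0:
        warnings.warn("both masks empty; Jaccard defined as 1", stacklevel=2)
        return 1.0
    return int((a & b).sum()) / union


def hausdorff_distance(a, b) -> float:
    """Symmetric Hausdorff distance (voxels) between nonzero voxel sets."""
    a, b = _as_binary(a), _as_binary(b)
    pa = np.argwhere(a).astype(float)
    pb = np.argwhere(b).astype(float)
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("Hausdorff distance undefined for an empty mask")
    return max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0])


@dataclass
class MetricReport:
    dice: float
    jaccard: float
    hausdorff: float


def evaluate_pair(pred, truth) -> MetricReport:
    return MetricReport(dice=dice_coefficient(pred, truth),
                        jaccard=jaccard_index(pred, truth),
                        hausdorff=hausdorff_distance(pred, truth))


def write_metrics_csv(rows, path):
    """rows: iterable of (subject, method, MetricReport)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject", "method", "dice", "jaccard", "hausdorff"])
        for subject, method, rep in rows:
            w.writerow([subject, method, rep.dice, rep.jaccard, rep.hausdorff])
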