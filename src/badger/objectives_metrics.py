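"""Training objectives and ranking metrics.

The training loss per instance is ``L = L1 + α·L2`` where

* ``L1 = RankCosine(Ŷ_G, Y_G) + MSE(Ŷ_G, Y_G)`` — a hybrid of a
  learning-to-rank loss (half the cosine distance between the predicted and
  true signed profiles) and mean squared error;
* ``L2`` — mean binary cross-entropy between the per-pathway attention
  association scores Ŷ_P and the binary drug–pathway labels Y_P (the
  attention regularizer), weighted by ``α`` (default 0.05).

Ranking quality is scored with NDCG and precision-at-K on a 0–100 scale,
separately for up- and down-regulated genes; down-regulation reuses the
up-direction machinery on negated vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._autodiff import Tensor

__all__ = [
    "LossBreakdown", "MetricsTable", "rank_cosine_loss", "mse_loss",
    "attention_reg_loss", "total_loss", "ndcg_score", "precision_at_k",
    "DEFAULT_ALPHA", "DEFAULT_REF_SIZE", "DEFAULT_K_LIST",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_REF_SIZE = 200
DEFAULT_K_LIST = (10, 50, 100, 200)
_CLAMP = 1e-7


@dataclass
class LossBreakdown:
    rank_cosine: float
    mse: float
    l2: float
    alpha: float

    @property
    def l1(self) -> float:
        return self.rank_cosine + self.mse

    @property
    def total(self) -> float:
        return self.l1 + self.alpha * self.l2


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def _maybe_float(t: Tensor, want_tensor: bool) -> Union[Tensor, float]:
    return t if want_tensor else float(t.item())


def rank_cosine_loss(pred, truth, *, as_tensor: bool = False):
    """½(1 − cos(pred, truth)) ∈ [0,1]; 0 iff the vectors are positively
    parallel.  A zero-norm prediction is treated as orthogonal (0.5)."""
    p, t = _as_tensor(pred), _as_tensor(truth)
    if p.shape != t.shape:
        raise ValueError("prediction and truth must have equal length")
    t_norm = float(np.linalg.norm(t.numpy()))
    if t_norm == 0.0:
        raise ValueError("truth profile is all-zero; cosine undefined")
    p_norm_val = float(np.linalg.norm(p.numpy()))
    if p_norm_val == 0.0:
        logger.warning("zero-norm prediction: RankCosine defined as 0.5")
        return _maybe_float(Tensor(0.5), as_tensor)
    p_norm = (p * p).sum().pow(0.5)
    cos = (p * t).sum() * (1.0 / t_norm) * p_norm.pow(-1.0)
    return _maybe_float((Tensor(1.0) - cos) * 0.5, as_tensor)


def mse_loss(pred, truth, *, as_tensor: bool = False):
    """Mean squared error."""
    p, t = _as_tensor(pred), _as_tensor(truth)
    if p.shape != t.shape:
        raise ValueError("prediction and truth must have equal length")
    d = p - t
    return _maybe_float((d * d).mean(), as_tensor)


def attention_reg_loss(association_scores, pathway_labels, *,
                       as_tensor: bool = False):
    """Mean binary cross-entropy of the pathway association scores against
    binary drug–pathway labels; scores are clamped away from {0,1}."""
    labels = np.asarray(pathway_labels, dtype=float)
    if not np.isin(labels, [0.0, 1.0]).all():
        raise ValueError("pathway labels must be binary")
    s = _as_tensor(association_scores)
    if s.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    clamped = s.numpy()
    lo = clamped < _CLAMP
    hi = clamped > 1.0 - _CLAMP
    if lo.any() or hi.any():
        # clamp without breaking the graph: shift the offending entries
        shift = np.zeros_like(clamped)
        shift[lo] = _CLAMP - clamped[lo]
        shift[hi] = (1.0 - _CLAMP) - clamped[hi]
        s = s + Tensor(shift)
    y = Tensor(labels)
    ll = y * s.log() + (Tensor(1.0) - y) * (Tensor(1.0) - s).log()
    return _maybe_float(-ll.mean(), as_tensor)


def total_loss(pred, truth, association_scores=None, pathway_labels=None,
               alpha: float = DEFAULT_ALPHA
               ) -> tuple[Union[Tensor, None], LossBreakdown]:
    """Full objective.  Returns the scalar loss tensor (when inputs are
    tensors) and a float breakdown.  Instances without pathway labels (or a
    model without the pathway block) contribute ``L2 = 0``."""
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    rc = rank_cosine_loss(pred, truth, as_tensor=True)
    mse = mse_loss(pred, truth, as_tensor=True)
    l1 = rc + mse
    if association_scores is not None and pathway_labels is not None:
        l2 = attention_reg_loss(association_scores, pathway_labels,
                                as_tensor=True)
        tot = l1 + l2 * alpha
        l2_val = float(l2.item())
    else:
        tot = l1
        l2_val = 0.0
    breakdown = LossBreakdown(rank_cosine=float(rc.item()),
                              mse=float(mse.item()), l2=l2_val, alpha=alpha)
    return tot, breakdown


# ------------------------------------------------------------------ metrics

def _sign(direction: str) -> float:
    if direction == "up":
        return 1.0
    if direction == "down":
        return -1.0
    raise ValueError("direction must be 'up' or 'down'")


def _ranked_indices(values: np.ndarray) -> np.ndarray:
    """Indices sorted by value descending, ties broken by ascending index."""
    n = len(values)
    order = np.lexsort((np.arange(n), -values))
    return order


def ndcg_score(pred, truth, direction: str = "up",
               ref_size: Optional[int] = None) -> float:
    """Normalized discounted cumulative gain on a 0–100 scale.

    Relevance of gene *i* is ``max(s·truth_i, 0)`` with *s* = +1 (up) or −1
    (down); genes are ranked by ``s·pred`` descending (ties by gene index)
    and discounted by ``log2(rank+1)`` over the full list.  All-zero
    relevance (no gene changed in that direction) scores a vacuous 100.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 1 or len(pred) < 2:
        raise ValueError("pred and truth must be equal-length vectors (n≥2)")
    s = _sign(direction)
    rel = np.maximum(s * truth, 0.0)
    if rel.sum() == 0.0:
        logger.warning("all relevances zero; NDCG defined as 100")
        return 100.0
    discounts = 1.0 / np.log2(np.arange(2, len(pred) + 2))
    dcg = float(rel[_ranked_indices(s * pred)] @ discounts)
    idcg = float(np.sort(rel)[::-1] @ discounts)
    return 100.0 * dcg / idcg


def precision_at_k(pred, truth, k: int, direction: str = "up",
                   ref_size: int = DEFAULT_REF_SIZE) -> float:
    """Percentage of the top-k predicted genes (by signed value in the given
    direction) found in the truth's top-``ref_size`` set."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    n = len(pred)
    if pred.shape != truth.shape or k > n or ref_size > n:
        raise ValueError("need equal lengths with k and ref_size <= n")
    s = _sign(direction)
    top_pred = set(_ranked_indices(s * pred)[:k].tolist())
    top_ref = set(_ranked_indices(s * truth)[:ref_size].tolist())
    return 100.0 * len(top_pred & top_ref) / k


@dataclass
class MetricsTable:
    """Fold-aggregated ranking metrics, shaped like the evaluation tables:
    one row per (direction), NDCG plus P@K columns, mean ± sd over folds."""

    k_list: Sequence[int] = DEFAULT_K_LIST
    fold_values: dict[str, list[float]] = field(default_factory=dict)

    def add_fold(self, direction: str, ndcg: float, p_at_k: dict[int, float]
                 ) -> None:
        self.fold_values.setdefault(f"{direction}:ndcg", []).append(ndcg)
        for k, v in p_at_k.items():
            self.fold_values.setdefault(f"{direction}:p@{k}", []).append(v)

    def summary(self) -> pd.DataFrame:
        rows = []
        for direction in ("up", "down"):
            row: dict[str, object] = {"direction": direction}
            for key in ([f"{direction}:ndcg"]
                        + [f"{direction}:p@{k}" for k in self.k_list]):
                vals = self.fold_values.get(key, [])
                col = key.split(":", 1)[1]
                if vals:
                    row[f"{col}_mean"] = float(np.mean(vals))
                    row[f"{col}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
                else:
                    row[f"{col}_mean"] = np.nan
                    row[f"{col}_sd"] = np.nan
            rows.append(row)
        return pd.DataFrame(rows)
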