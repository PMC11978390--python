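"""Cross-validation splits, the training loop and fold-wise evaluation.

Three split regimes mirror the generalization questions the model is asked:
``new_cell`` holds out whole cell lines, ``new_drug`` whole molecules, and
``new_pair`` both simultaneously (test instances pair a held-out cell with a
held-out drug; instances mixing seen and unseen entities are discarded).

Training minimizes ``L1 + α·L2`` with Adam, one fold at a time.  Anchor
cells for the similarity embedding are always the training-fold cells only:
a test cell line is embedded by its similarity to training anchors, never by
identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .core_data import PerturbationDataset
from .network import Badger, ModelConfig
from .nn import Adam
from .objectives_metrics import (DEFAULT_ALPHA, DEFAULT_K_LIST,
                                 DEFAULT_REF_SIZE, MetricsTable, ndcg_score,
                                 precision_at_k, total_loss)

__all__ = ["SplitSpec", "TrainConfig", "FoldResult", "make_cv_folds",
           "train_model", "evaluate_model", "aggregate_metrics"]

logger = logging.getLogger(__name__)

SPLIT_MODES = ("new_cell", "new_drug", "new_pair")


@dataclass
class SplitSpec:
    mode: str = "new_pair"
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.mode not in SPLIT_MODES:
            raise ValueError(f"mode must be one of {SPLIT_MODES}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class TrainConfig:
    lr: float = 1e-4
    batch_size: int = 64
    max_epochs: int = 100
    alpha: float = DEFAULT_ALPHA
    seed: int = 0
    max_steps: Optional[int] = None      # cap on optimizer steps, if set
    clip_norm: float = 5.0
    device: str = "cpu"                  # hint only; execution is numpy

    def __post_init__(self):
        if self.lr <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("lr, batch_size and max_epochs must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")


@dataclass
class FoldResult:
    fold: int
    model: Badger
    history: pd.DataFrame                 # per-epoch loss breakdown
    train_idx: list[int]
    test_idx: list[int]
    anchor_cell_ids: list[str]


def _partition(entities: list[str], n_folds: int,
               rng: np.random.Generator) -> list[set[str]]:
    order = list(entities)
    rng.shuffle(order)
    return [set(order[i::n_folds]) for i in range(n_folds)]


def make_cv_folds(dataset: PerturbationDataset, spec: SplitSpec
                  ) -> list[tuple[list[int], list[int]]]:
    """Seeded grouped cross-validation folds as (train_idx, test_idx) lists.

    Leakage is asserted: in every fold, the entity type named by the mode
    never occurs on both sides.
    """
    cells = sorted({i.cell_id for i in dataset.instances})
    drugs = sorted({i.molecule_smiles for i in dataset.instances})
    rng = np.random.default_rng(spec.seed)
    if spec.mode in ("new_cell", "new_pair") and len(cells) < spec.n_folds:
        raise ValueError(f"{len(cells)} distinct cells < {spec.n_folds} folds")
    if spec.mode in ("new_drug", "new_pair") and len(drugs) < spec.n_folds:
        raise ValueError(f"{len(drugs)} distinct drugs < {spec.n_folds} folds")

    folds = []
    if spec.mode == "new_pair":
        cell_groups = _partition(cells, spec.n_folds, rng)
        drug_groups = _partition(drugs, spec.n_folds, rng)
        for f in range(spec.n_folds):
            tc, td = cell_groups[f], drug_groups[f]
            train, test, discard = [], [], 0
            for i, inst in enumerate(dataset.instances):
                in_c, in_d = inst.cell_id in tc, inst.molecule_smiles in td
                if in_c and in_d:
                    test.append(i)
                elif not in_c and not in_d:
                    train.append(i)
                else:
                    discard += 1
            logger.info("new_pair fold %d: %d train, %d test, %d discarded",
                        f, len(train), len(test), discard)
            folds.append((train, test))
    else:
        key = ((lambda i: i.cell_id) if spec.mode == "new_cell"
               else (lambda i: i.molecule_smiles))
        groups = _partition(cells if spec.mode == "new_cell" else drugs,
                            spec.n_folds, rng)
        for f in range(spec.n_folds):
            held = groups[f]
            test = [i for i, inst in enumerate(dataset.instances)
                    if key(inst) in held]
            train = [i for i, inst in enumerate(dataset.instances)
                     if key(inst) not in held]
            folds.append((train, test))

    for train, test in folds:   # hard leakage check
        tr = dataset.subset(train).instances
        te = dataset.subset(test).instances
        if spec.mode in ("new_cell", "new_pair"):
            assert not ({i.cell_id for i in tr} & {i.cell_id for i in te}), \
                "cell leakage across split"
        if spec.mode in ("new_drug", "new_pair"):
            assert not ({i.molecule_smiles for i in tr}
                        & {i.molecule_smiles for i in te}), \
                "drug leakage across split"
    return folds


def _build_features(dataset: PerturbationDataset, idx: Sequence[int],
                    anchor_profiles: pd.DataFrame,
                    featurizer: Callable[[str], np.ndarray]
                    ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-instance fingerprint matrices and similarity vectors, cached per
    unique molecule / cell."""
    from . import featurize as fz
    f_cache: dict[str, np.ndarray] = {}
    s_cache: dict[str, np.ndarray] = {}
    fps, sims = [], []
    for i in idx:
        inst = dataset.instances[i]
        tok = inst.molecule_smiles
        if tok not in f_cache:
            f_cache[tok] = featurizer(tok)
        if inst.cell_id not in s_cache:
            profile = dataset.basal_expression[inst.cell_id]
            s_cache[inst.cell_id] = fz.cell_similarity_vector(
                inst.cell_id, profile, anchor_profiles).values
        fps.append(f_cache[tok])
        sims.append(s_cache[inst.cell_id])
    return fps, sims


def train_model(dataset: PerturbationDataset, model_config: ModelConfig,
                train_config: TrainConfig,
                folds: Sequence[tuple[Sequence[int], Sequence[int]]],
                featurizer: Callable[[str], np.ndarray],
                anchor_mode: str = "train_only",
                ) -> list[FoldResult]:
    """Train one model per fold; returns models with per-epoch histories.

    ``featurizer`` maps a molecule token to its k × n_bits fingerprint
    matrix (BRICS+Morgan for SMILES, vocabulary lookup for synthetic
    worlds).  ``anchor_mode`` selects the similarity anchor panel:
    ``train_only`` (default, no test-cell information in the embedding) or
    ``all`` (the permissive variant using every cell in the basal matrix).
    """
    if dataset.basal_expression is None:
        raise ValueError("dataset needs a basal expression matrix")
    if anchor_mode not in ("train_only", "all"):
        raise ValueError("anchor_mode must be 'train_only' or 'all'")
    results = []
    for f, (train_idx, test_idx) in enumerate(folds):
        if anchor_mode == "all":
            anchors = list(dataset.basal_expression.columns)
        else:
            anchors = sorted({dataset.instances[i].cell_id
                              for i in train_idx})
        anchor_profiles = dataset.basal_expression[anchors]
        cfg = replace(model_config, n_anchors=len(anchors),
                      seed=model_config.seed + f)
        model = Badger(cfg)
        fps, sims = _build_features(dataset, train_idx, anchor_profiles,
                                    featurizer)
        labels = [dataset.instances[i].pathway_labels for i in train_idx]
        truths = [dataset.instances[i].deg_profile for i in train_idx]
        opt = Adam(model.parameters(), lr=train_config.lr,
                   clip_norm=train_config.clip_norm)
        rng = np.random.default_rng(train_config.seed + f)
        n = len(train_idx)
        history_rows = []
        steps = 0
        done = False
        for epoch in range(train_config.max_epochs):
            order = rng.permutation(n)
            ep = {"rank_cosine": 0.0, "mse": 0.0, "l2": 0.0, "total": 0.0,
                  "count": 0}
            for start in range(0, n, train_config.batch_size):
                batch = order[start:start + train_config.batch_size]
                opt.zero_grad()
                model.zero_grad()
                batch_loss = None
                for j in batch:
                    y_hat, assoc, _ = model.forward(fps[j], sims[j])
                    use_labels = (assoc is not None and labels[j] is not None
                                  and train_config.alpha > 0)
                    loss, bd = total_loss(
                        y_hat, truths[j],
                        assoc if use_labels else None,
                        labels[j] if use_labels else None,
                        alpha=train_config.alpha)
                    if not np.isfinite(bd.total):
                        raise FloatingPointError(
                            f"non-finite loss at fold {f} epoch {epoch} "
                            f"instance {train_idx[j]}: {bd}")
                    batch_loss = loss if batch_loss is None else batch_loss + loss
                    ep["rank_cosine"] += bd.rank_cosine
                    ep["mse"] += bd.mse
                    ep["l2"] += bd.l2
                    ep["total"] += bd.total
                    ep["count"] += 1
                (batch_loss * (1.0 / len(batch))).backward()
                opt.step()
                steps += 1
                if (train_config.max_steps is not None
                        and steps >= train_config.max_steps):
                    done = True
                    break
            c = max(ep["count"], 1)
            history_rows.append({
                "epoch": epoch, "steps": steps,
                "rank_cosine": ep["rank_cosine"] / c, "mse": ep["mse"] / c,
                "l1": (ep["rank_cosine"] + ep["mse"]) / c,
                "l2": ep["l2"] / c, "total": ep["total"] / c})
            if done:
                break
        model.eval()
        results.append(FoldResult(
            fold=f, model=model, history=pd.DataFrame(history_rows),
            train_idx=list(train_idx), test_idx=list(test_idx),
            anchor_cell_ids=anchors))
    return results


def evaluate_model(model: Badger, dataset: PerturbationDataset,
                   test_idx: Sequence[int],
                   anchor_cell_ids: Sequence[str],
                   featurizer: Callable[[str], np.ndarray],
                   k_list: Sequence[int] = DEFAULT_K_LIST,
                   ref_size: int = DEFAULT_REF_SIZE) -> dict[str, float]:
    """Mean per-instance ranking metrics over one test fold.

    Returns a flat dict keyed ``up:ndcg``, ``up:p@10`` etc.  ``k_list`` and
    ``ref_size`` must not exceed the gene count (scale them down for small
    synthetic gene panels).
    """
    anchor_profiles = dataset.basal_expression[list(anchor_cell_ids)]
    fps, sims = _build_features(dataset, test_idx, anchor_profiles,
                                featurizer)
    per_key: dict[str, list[float]] = {}
    for pos, i in enumerate(test_idx):
        truth = dataset.instances[i].deg_profile
        out = model.predict(fps[pos], sims[pos])
        for direction in ("up", "down"):
            per_key.setdefault(f"{direction}:ndcg", []).append(
                ndcg_score(out.predicted_profile, truth, direction))
            for k in k_list:
                per_key.setdefault(f"{direction}:p@{k}", []).append(
                    precision_at_k(out.predicted_profile, truth, k,
                                   direction, ref_size))
    return {k: float(np.mean(v)) for k, v in per_key.items()}


def aggregate_metrics(fold_metrics: Sequence[dict[str, float]],
                      k_list: Sequence[int] = DEFAULT_K_LIST) -> MetricsTable:
    """Collect per-fold metric dicts into a mean ± sd table."""
    table = MetricsTable(k_list=list(k_list))
    for m in fold_metrics:
        for direction in ("up", "down"):
            table.add_fold(direction, m[f"{direction}:ndcg"],
                           {k: m[f"{direction}:p@{k}"] for k in k_list})
    return table
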