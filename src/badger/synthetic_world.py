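"""Seeded generator of perturbation datasets with planted structure.

The generative model mirrors the mechanism the ranking network assumes:
drugs are bags of fragments, fragments associate with pathways, pathways
push their member genes up or down with a pathway-wise signed effect size,
modulated multiplicatively per cell line, plus i.i.d. Gaussian noise:

    y_g = Σ_{p active for the drug} β_p · m_{c,p} · member_{p,g} + ε_g

A drug's binary pathway label vector is the union of its fragments'
pathway associations — exactly the quantity the attention regularizer is
supposed to recover.

Two molecule modes are supported: ``abstract`` (drugs are fragment-index
bags with random binary fingerprints; no chemistry involved) and
``smiles`` (drugs assembled from a built-in list of parseable fragment
SMILES so the BRICS/Morgan code paths are exercised).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import core_data
from .core_data import PerturbationDataset, PerturbationInstance

__all__ = ["SyntheticWorld", "generate_world", "generate_dataset",
           "fragment_featurizer", "recovery_report", "DEFAULT_WORLD",
           "FRAGMENT_SMILES_POOL"]

# defaults for the reference synthetic benchmark
DEFAULT_WORLD = dict(n_drugs=40, n_cells=6, n_pathways=12, n_genes=60,
                     v_fragments=16, sparsity=0.12, noise_sd=0.1)

# small parseable fragments for `smiles` mode (plain valid SMILES)
FRAGMENT_SMILES_POOL = [
    "CCO", "CCN", "CCC", "c1ccccc1", "c1ccncc1", "C1CCCCC1", "C1CCNCC1",
    "CC(C)O", "CC(C)N", "CC(=O)O", "CC(=O)N", "CCS", "CCF", "CCCl",
    "c1ccc(O)cc1", "c1ccc(N)cc1", "c1ccc(F)cc1", "c1ccc(Cl)cc1",
    "CC(C)C", "CCCC", "CCCO", "CCCN", "C1CCOC1", "C1CCNC1", "CC=O",
    "c1ccsc1", "c1cc[nH]c1", "c1ccoc1", "CC#N", "CCBr", "C1CC1", "C1CCC1",
    "CC(C)=O", "COC", "CCOC", "CN(C)C", "CCNC", "c1cnccn1", "c1ccc2ccccc2c1",
    "CC(N)=O", "CS(C)=O", "OCCO", "NCCN", "OCCN", "CC(O)C", "CCCCC",
    "c1cncnc1", "C1COCCN1", "CC(C)(C)C", "c1cscn1",
]


@dataclass
class SyntheticWorld:
    """Planted ground truth from which datasets are sampled."""

    fragment_fingerprints: np.ndarray     # V × n_bits binary
    fragment_to_pathways: np.ndarray      # V × n_pathways binary
    drugs: list[list[int]]                # fragment-index bags
    drug_smiles: Optional[list[str]]      # only in `smiles` mode
    pathway_members: np.ndarray           # n_pathways × n_genes binary
    effect_sizes: np.ndarray              # β, signed, per pathway
    cell_modifiers: np.ndarray            # n_cells × n_pathways, positive
    noise_sd: float
    seed: int
    gene_ids: list[str] = field(default_factory=list)
    pathway_ids: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)
    basal_expression: Optional[pd.DataFrame] = None

    @property
    def n_pathways(self) -> int:
        return self.fragment_to_pathways.shape[1]

    @property
    def n_genes(self) -> int:
        return self.pathway_members.shape[1]

    @property
    def n_bits(self) -> int:
        return self.fragment_fingerprints.shape[1]

    def drug_labels(self, drug_idx: int) -> np.ndarray:
        """Binary pathway label vector: union over the drug's fragments."""
        frags = self.drugs[drug_idx]
        return (self.fragment_to_pathways[frags].sum(axis=0) > 0).astype(float)

    def drug_token(self, drug_idx: int) -> str:
        """The molecule identifier written into the dataset's smiles column."""
        if self.drug_smiles is not None:
            return self.drug_smiles[drug_idx]
        return "frag:" + "+".join(str(f) for f in self.drugs[drug_idx])

    def mean_profile(self, drug_idx: int, cell_idx: int) -> np.ndarray:
        """Noise-free expected DEG profile for one (drug, cell) pair."""
        labels = self.drug_labels(drug_idx)
        weights = labels * self.effect_sizes * self.cell_modifiers[cell_idx]
        return weights @ self.pathway_members

    def to_json(self, path) -> None:
        blob = {
            "seed": self.seed, "noise_sd": self.noise_sd,
            "drugs": self.drugs, "drug_smiles": self.drug_smiles,
            "fragment_fingerprints": self.fragment_fingerprints.tolist(),
            "fragment_to_pathways": self.fragment_to_pathways.tolist(),
            "pathway_members": self.pathway_members.tolist(),
            "effect_sizes": self.effect_sizes.tolist(),
            "cell_modifiers": self.cell_modifiers.tolist(),
            "gene_ids": self.gene_ids, "pathway_ids": self.pathway_ids,
            "cell_ids": self.cell_ids,
        }
        Path(path).write_text(json.dumps(blob))


def generate_world(n_drugs: int = DEFAULT_WORLD["n_drugs"],
                   n_cells: int = DEFAULT_WORLD["n_cells"],
                   n_pathways: int = DEFAULT_WORLD["n_pathways"],
                   n_genes: int = DEFAULT_WORLD["n_genes"],
                   v_fragments: int = DEFAULT_WORLD["v_fragments"],
                   sparsity: float = DEFAULT_WORLD["sparsity"],
                   noise_sd: float = DEFAULT_WORLD["noise_sd"],
                   seed: int = 0,
                   n_bits: int = 64,
                   fragments_per_drug: tuple[int, int] = (2, 4),
                   cell_modifier_sd: float = 0.4,
                   molecule_mode: str = "abstract",
                   ensure_reachable: bool = True) -> SyntheticWorld:
    """Draw a seeded world with planted fragment→pathway→gene structure.

    ``sparsity`` is the Bernoulli rate of fragment–pathway links.  Pathway
    member-gene blocks are disjoint when ``n_genes`` allows, overlapping
    otherwise.  Effect-size signs are balanced so both up- and
    down-regulation occur.
    """
    if min(n_drugs, n_cells, n_pathways, n_genes, v_fragments) < 1:
        raise ValueError("all counts must be >= 1")
    if not 0.0 < sparsity < 1.0:
        raise ValueError("sparsity must be in (0,1)")
    if molecule_mode not in ("abstract", "smiles"):
        raise ValueError("molecule_mode must be 'abstract' or 'smiles'")
    rng = np.random.default_rng(seed)

    if molecule_mode == "smiles":
        if v_fragments > len(FRAGMENT_SMILES_POOL):
            raise ValueError(
                f"at most {len(FRAGMENT_SMILES_POOL)} fragments available in "
                "smiles mode")
        from . import featurize as fz
        pool = FRAGMENT_SMILES_POOL[:v_fragments]
        fps = fz.fragment_fingerprints(pool, n_bits=n_bits)
    else:
        pool = None
        # distinct random binary codes, ~25% density
        fps = (rng.random((v_fragments, n_bits)) < 0.25).astype(float)

    f2p = (rng.random((v_fragments, n_pathways)) < sparsity).astype(float)
    if ensure_reachable:
        # every pathway reachable through at least one fragment
        for p in range(n_pathways):
            if f2p[:, p].sum() == 0:
                f2p[rng.integers(v_fragments), p] = 1.0

    lo, hi = fragments_per_drug
    drugs = []
    for _ in range(n_drugs):
        k = int(rng.integers(lo, hi + 1))
        drugs.append(sorted(rng.choice(v_fragments, size=k,
                                       replace=False).tolist()))
    drug_smiles = None
    if molecule_mode == "smiles":
        drug_smiles = [".".join(pool[f] for f in bag) for bag in drugs]

    # pathway membership: equal blocks, disjoint if they fit
    members = np.zeros((n_pathways, n_genes))
    block = max(1, n_genes // n_pathways)
    if block * n_pathways <= n_genes:
        for p in range(n_pathways):
            members[p, p * block:(p + 1) * block] = 1.0
    else:
        for p in range(n_pathways):
            members[p, rng.choice(n_genes, size=block, replace=False)] = 1.0

    mags = rng.uniform(0.5, 1.5, size=n_pathways)
    signs = np.ones(n_pathways)
    signs[n_pathways // 2:] = -1.0
    rng.shuffle(signs)
    beta = mags * signs
    modifiers = rng.lognormal(0.0, cell_modifier_sd,
                              size=(n_cells, n_pathways))
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    pathway_ids = [f"PW{p:03d}" for p in range(n_pathways)]
    cell_ids = [f"CELL{c:02d}" for c in range(n_cells)]
    # basal expression: pathway-structured so Spearman similarity is
    # informative about shared modifiers, plus gene-level variation
    basal = (modifiers @ members) + rng.normal(0.0, 0.3, (n_cells, n_genes))
    basal_df = pd.DataFrame(basal.T, index=gene_ids, columns=cell_ids)
    return SyntheticWorld(
        fragment_fingerprints=fps, fragment_to_pathways=f2p, drugs=drugs,
        drug_smiles=drug_smiles, pathway_members=members, effect_sizes=beta,
        cell_modifiers=modifiers, noise_sd=noise_sd, seed=seed,
        gene_ids=gene_ids, pathway_ids=pathway_ids, cell_ids=cell_ids,
        basal_expression=basal_df)


def generate_dataset(world: SyntheticWorld, n_instances: int = 240,
                     seed: int = 0, tas_below_threshold_rate: float = 0.0,
                     qc_fail_rate: float = 0.0,
                     off_dose_rate: float = 0.0) -> PerturbationDataset:
    """Sample (drug, cell) instances from a world.

    By default every instance passes the preprocessing cascade (dose 10 μM,
    time 24 h, QC pass, TAS > 0.2); the contamination rates flip a seeded
    fraction of instances to fail each filter, for testing the cascade.
    """
    rng = np.random.default_rng(seed)
    instances = []
    for _ in range(n_instances):
        d = int(rng.integers(len(world.drugs)))
        c = int(rng.integers(len(world.cell_ids)))
        profile = world.mean_profile(d, c)
        if world.noise_sd > 0:
            profile = profile + rng.normal(0.0, world.noise_sd,
                                           size=world.n_genes)
        dose, time_h, qc = 10.0, 24.0, True
        tas = float(rng.uniform(0.3, 1.0))
        if off_dose_rate and rng.random() < off_dose_rate:
            dose = float(rng.choice([0.1, 1.0, 5.0]))
        if qc_fail_rate and rng.random() < qc_fail_rate:
            qc = False
        if tas_below_threshold_rate and rng.random() < tas_below_threshold_rate:
            tas = float(rng.uniform(0.0, 0.2))
        instances.append(PerturbationInstance(
            molecule_smiles=world.drug_token(d), cell_id=world.cell_ids[c],
            dose=dose, time=time_h, qc_pass=qc, tas=tas,
            deg_profile=profile, pathway_labels=world.drug_labels(d)))
    return PerturbationDataset(
        instances=instances, gene_ids=list(world.gene_ids),
        pathway_ids=list(world.pathway_ids),
        anchor_cell_ids=list(world.cell_ids),
        basal_expression=world.basal_expression)


def fragment_featurizer(world: SyntheticWorld):
    """Featurizer mapping a dataset's molecule token to its fingerprint
    matrix F (k × n_bits).  Abstract tokens (``frag:i+j+...``) index the
    world's fragment vocabulary; anything else goes through BRICS + Morgan.
    """
    def featurize(token: str) -> np.ndarray:
        if token.startswith("frag:"):
            idx = [int(t) for t in token[5:].split("+")]
            return world.fragment_fingerprints[idx]
        from . import featurize as fz
        return fz.featurize_molecule(token, n_bits=world.n_bits).fingerprints
    return featurize


def write_world_files(world: SyntheticWorld, dataset: PerturbationDataset,
                      out_dir) -> dict[str, Path]:
    """Write the dataset in the package's on-disk schemata: perturbation
    TSV, GMT pathway sets, basal TSV, drug→pathway map and the planted
    truth as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "perturbations": out / "perturbations.tsv",
        "pathways": out / "pathways.gmt",
        "basal": out / "basal_expression.tsv",
        "drug_pathways": out / "drug_pathways.tsv",
        "world": out / "world.json",
    }
    core_data.write_perturbation_table(dataset, paths["perturbations"])
    sets = {pid: {world.gene_ids[g]
                  for g in np.flatnonzero(world.pathway_members[p])}
            for p, pid in enumerate(world.pathway_ids)}
    core_data.write_gene_sets_gmt(sets, paths["pathways"])
    core_data.write_basal_expression(world.basal_expression, paths["basal"])
    with open(paths["drug_pathways"], "w") as fh:
        for d in range(len(world.drugs)):
            token = world.drug_token(d)
            for p in np.flatnonzero(world.drug_labels(d)):
                fh.write(f"{token}\t{world.pathway_ids[p]}\n")
    world.to_json(paths["world"])
    return paths


def recovery_report(model, world: SyntheticWorld,
                    held_out: PerturbationDataset,
                    anchor_profiles: pd.DataFrame,
                    n_null: int = 200, seed: int = 0,
                    sim_cache: Optional[dict] = None) -> dict:
    """How well a trained model recovers the planted structure.

    Reports (a) AUROC of the pathway association scores Ŷ_P against the
    planted binary labels over held-out instances, (b) mean NDCG (up/down
    averaged) of Ŷ_G against the planted profiles, and (c) the same NDCG
    under a permuted pairing of predictions to truths (null).
    """
    from sklearn.metrics import roc_auc_score
    from . import featurize as fz
    from .objectives_metrics import ndcg_score

    featurize = fragment_featurizer(world)
    rng = np.random.default_rng(seed)
    scores, labels, preds, truths = [], [], [], []
    sim_cache = {} if sim_cache is None else sim_cache
    for inst in held_out.instances:
        if inst.cell_id not in sim_cache:
            sim_cache[inst.cell_id] = fz.cell_similarity_vector(
                inst.cell_id, anchor_profiles[inst.cell_id]
                if inst.cell_id in anchor_profiles.columns else
                held_out.basal_expression[inst.cell_id],
                anchor_profiles).values
        out = model.predict(featurize(inst.molecule_smiles),
                            sim_cache[inst.cell_id])
        preds.append(out.predicted_profile)
        truths.append(inst.deg_profile)
        if out.association_scores is not None and inst.pathway_labels is not None:
            scores.append(out.association_scores)
            labels.append(inst.pathway_labels)

    report: dict = {"n_instances": len(held_out.instances)}
    if labels:
        lab = np.concatenate(labels)
        if lab.min() == lab.max():
            report["pathway_auroc"] = None   # degenerate labels
        else:
            report["pathway_auroc"] = float(
                roc_auc_score(lab, np.concatenate(scores)))
    else:
        report["pathway_auroc"] = None

    def mean_ndcg(pairing: np.ndarray) -> float:
        vals = []
        for i, j in enumerate(pairing):
            for direction in ("up", "down"):
                vals.append(ndcg_score(preds[i], truths[j], direction))
        return float(np.mean(vals))

    n = len(preds)
    report["ndcg"] = mean_ndcg(np.arange(n))
    null_vals = []
    n_null_perms = max(1, n_null // n)
    for _ in range(n_null_perms):
        null_vals.append(mean_ndcg(rng.permutation(n)))
    report["ndcg_null"] = float(np.mean(null_vals))
    report["ndcg_gap"] = report["ndcg"] - report["ndcg_null"]
    return report


# ---------------------------------------------------- reference benchmark

# model and optimizer settings for the default recovery benchmark: a small
# model matched to the default world's scale, trained for a fixed budget of
# 300 Adam steps.  The step size is larger than the full-scale training
# default because the benchmark model/dataset are orders of magnitude
# smaller.
BENCHMARK_MODEL = dict(embed_dim=32, n_heads=2, mlp_hidden=64, head_hidden=8,
                       dropout=0.1)
BENCHMARK_TRAIN = dict(lr=3e-3, batch_size=64, max_epochs=400, alpha=0.05,
                       max_steps=300)
BENCHMARK_N_INSTANCES = 240


def run_recovery_benchmark(seed: int, use_ppab: bool = True) -> dict:
    """Train on the default world (held-out-drug split, fold 0) and report
    planted-structure recovery; the reference check for the whole pipeline.

    Returns the :func:`recovery_report` dict plus the training history tail.
    """
    from .experiment import SplitSpec, TrainConfig, make_cv_folds, train_model
    from .network import ModelConfig

    world = generate_world(seed=seed)
    ds = generate_dataset(world, n_instances=BENCHMARK_N_INSTANCES, seed=seed)
    folds = make_cv_folds(ds, SplitSpec("new_drug", n_folds=5, seed=seed))
    mc = ModelConfig(n_genes=world.n_genes, n_pathways=world.n_pathways,
                     n_anchors=len(world.cell_ids), n_bits=world.n_bits,
                     seed=seed, use_ppab=use_ppab, **BENCHMARK_MODEL)
    tc = TrainConfig(seed=seed, **BENCHMARK_TRAIN)
    fold = train_model(ds, mc, tc, folds[:1], fragment_featurizer(world))[0]
    report = recovery_report(fold.model, world, ds.subset(fold.test_idx),
                             ds.basal_expression[fold.anchor_cell_ids],
                             seed=seed)
    report["final_l1"] = float(fold.history["l1"].iloc[-1])
    report["initial_l1"] = float(fold.history["l1"].iloc[0])
    report["use_ppab"] = use_ppab
    return report
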