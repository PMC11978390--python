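"""The DEG-ranking network.

A molecule (as BRICS-fragment Morgan fingerprints) and a cell line (as a
Spearman similarity vector against anchor cell lines) are encoded and fused
into fragment-wise perturbation embeddings, then passed through three
attention blocks:

* perturbation→pathway cross-attention (PPAB) with a learnable
  pseudo-fragment token that absorbs attention mass for pathways the drug
  does not touch — the head-averaged attention matrix ``A`` is the model's
  interpretable drug–pathway readout;
* pathway→gene cross-attention (PGAB) onto trainable landmark-gene
  embeddings;
* gene–gene self-attention (GGAB) enriching gene embeddings with pairwise
  gene relationships;

followed by one small feed-forward head per gene that emits that gene's
predicted signed differential-expression value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from ._autodiff import Tensor, concat
from .nn import MLP, Module, MultiheadAttention

__all__ = [
    "ModelConfig", "ForwardOutputs", "Badger", "pathway_association_scores",
    "save_checkpoint", "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``use_ppab=False`` removes the perturbation–pathway cross-attention
    block (ablation): pathway embeddings then feed the gene block directly
    and no attention readout is produced.
    """

    embed_dim: int = 128
    n_heads: int = 4
    dropout: float = 0.1
    mlp_hidden: int = 256
    head_hidden: int = 32
    n_genes: int = 978
    n_pathways: int = 140
    n_anchors: int = 114
    n_bits: int = 1024
    use_ppab: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        for name in ("embed_dim", "n_heads", "mlp_hidden", "head_hidden",
                     "n_genes", "n_pathways", "n_anchors", "n_bits"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0,1)")


@dataclass
class ForwardOutputs:
    """Prediction bundle for one instance."""

    predicted_profile: np.ndarray            # Ŷ_G, length n_genes
    attention: Optional[np.ndarray]          # A, n_pathways × (k+1); None w/o PPAB
    association_scores: Optional[np.ndarray]  # Ŷ_P, length n_pathways


def pathway_association_scores(A: np.ndarray, k: int) -> np.ndarray:
    """Per-pathway probability of drug association: the attention mass on
    the k real fragments (equivalently 1 − mass on the pseudo-fragment)."""
    A = np.asarray(A, dtype=float)
    if A.shape[1] != k + 1:
        raise ValueError(f"attention has {A.shape[1]} columns, expected k+1="
                         f"{k + 1}")
    return A[:, :k].sum(axis=1)


class _AttentionBlock(Module):
    """Pre-norm residual attention block (attention + position-wise MLP)."""

    def __init__(self, d: int, n_heads: int, mlp_hidden: int, dropout: float,
                 rng: np.random.Generator):
        super().__init__()
        self.mha = MultiheadAttention(d, n_heads, rng)
        self.ff = MLP(d, mlp_hidden, d, dropout, rng)

    def __call__(self, query: Tensor, kv: Tensor) -> tuple[Tensor, Tensor]:
        attended, A = self.mha(query.layer_norm(), kv.layer_norm(),
                               kv.layer_norm())
        x = query + attended
        x = x + self.ff(x.layer_norm())
        return x, A


class _GeneHeads(Module):
    """One two-layer feed-forward head per gene, evaluated as a batched
    matmul; head *i* sees only gene *i*'s embedding and parameters."""

    def __init__(self, n_genes: int, d: int, hidden: int,
                 rng: np.random.Generator):
        super().__init__()
        bound1 = np.sqrt(6.0 / (d + hidden))
        bound2 = np.sqrt(6.0 / (hidden + 1))
        self.w1 = Tensor(rng.uniform(-bound1, bound1, (n_genes, d, hidden)),
                         requires_grad=True)
        self.b1 = Tensor(np.zeros((n_genes, 1, hidden)), requires_grad=True)
        self.w2 = Tensor(rng.uniform(-bound2, bound2, (n_genes, hidden, 1)),
                         requires_grad=True)
        self.b2 = Tensor(np.zeros((n_genes, 1, 1)), requires_grad=True)
        self.n_genes, self.d = n_genes, d

    def __call__(self, x: Tensor) -> Tensor:
        h = x.reshape(self.n_genes, 1, self.d) @ self.w1 + self.b1
        y = h.gelu() @ self.w2 + self.b2
        return y.reshape(self.n_genes)


class Badger(Module):
    """Full model; see module docstring for the architecture."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.embed_dim
        self.mol_mlp = MLP(config.n_bits, config.mlp_hidden, d,
                           config.dropout, rng)
        self.cell_mlp = MLP(config.n_anchors, config.mlp_hidden, d,
                            config.dropout, rng)
        self.fuse_mc = MLP(2 * d, config.mlp_hidden, d, config.dropout, rng)
        self.fuse_mcg = MLP(2 * d, config.mlp_hidden, d, config.dropout, rng)
        self.pathway_table = Tensor(rng.normal(0.0, 0.02,
                                               (config.n_pathways, d)),
                                    requires_grad=True)
        self.gene_table = Tensor(rng.normal(0.0, 0.02, (config.n_genes, d)),
                                 requires_grad=True)
        self.pseudo_fragment = Tensor(rng.normal(0.0, 0.02, (1, d)),
                                      requires_grad=True)
        if config.use_ppab:
            self.ppab = _AttentionBlock(d, config.n_heads, config.mlp_hidden,
                                        config.dropout, rng)
        self.pgab = _AttentionBlock(d, config.n_heads, config.mlp_hidden,
                                    config.dropout, rng)
        self.ggab = _AttentionBlock(d, config.n_heads, config.mlp_hidden,
                                    config.dropout, rng)
        self.heads = _GeneHeads(config.n_genes, d, config.head_hidden, rng)

    # ------------------------------------------------------------- encoders
    def encode_molecule(self, fingerprints: np.ndarray) -> Tensor:
        """k × n_bits fragment fingerprints → k × d fragment embeddings."""
        F = np.asarray(fingerprints, dtype=float)
        if F.ndim != 2 or F.shape[1] != self.config.n_bits:
            raise ValueError(f"fingerprints must be k×{self.config.n_bits}, "
                             f"got {F.shape}")
        return self.mol_mlp(Tensor(F))

    def encode_cell(self, similarity: np.ndarray) -> Tensor:
        """Anchor-similarity vector → single d-dimensional cell embedding."""
        v = np.asarray(similarity, dtype=float)
        if v.shape != (self.config.n_anchors,):
            raise ValueError(f"similarity vector must have length "
                             f"{self.config.n_anchors}, got {v.shape}")
        return self.cell_mlp(Tensor(v.reshape(1, -1))).reshape(
            self.config.embed_dim)

    # --------------------------------------------------------------- fusion
    def fuse_molecule_cell(self, x_m: Tensor, x_c: Tensor) -> Tensor:
        """Row-repeat the cell embedding to k rows, concatenate with the
        fragment embeddings and fuse through an MLP (k × d output)."""
        k = x_m.shape[0]
        x_c_rep = x_c.reshape(1, -1) * Tensor(np.ones((k, 1)))
        return self.fuse_mc(concat([x_m, x_c_rep], axis=-1))

    def append_pseudo_fragment(self, x_mc: Tensor) -> Tensor:
        """Append the shared pseudo-fragment token as the last row."""
        return concat([x_mc, self.pseudo_fragment], axis=0)

    # ------------------------------------------------------------ attention
    def ppab_forward(self, x_mc_plus: Tensor) -> tuple[Tensor, Tensor]:
        """Perturbation→pathway cross-attention; pathways are queries.
        Returns contextualized pathway embeddings and the head-averaged
        attention matrix (n_pathways × (k+1))."""
        if not self.config.use_ppab:
            raise RuntimeError("model was built with use_ppab=False")
        return self.ppab(self.pathway_table, x_mc_plus)

    def pgab_forward(self, x_p: Tensor) -> tuple[Tensor, Tensor]:
        """Pathway→gene cross-attention; genes are queries."""
        return self.pgab(self.gene_table, x_p)

    def fuse_molecule_cell_gene(self, x_g: Tensor, x_mc: Tensor) -> Tensor:
        """Mean-pool the fragment-wise perturbation embeddings (pseudo row
        excluded), row-repeat and fuse with the gene embeddings."""
        pooled = x_mc.mean(axis=0)
        rep = pooled.reshape(1, -1) * Tensor(np.ones((x_g.shape[0], 1)))
        return self.fuse_mcg(concat([x_g, rep], axis=-1))

    def ggab_forward(self, x_g_star: Tensor) -> tuple[Tensor, Tensor]:
        """Gene–gene self-attention (no positional encoding, hence
        permutation-equivariant over gene rows)."""
        return self.ggab(x_g_star, x_g_star)

    def predict_gene_values(self, x_z: Tensor) -> Tensor:
        """Gene-wise feed-forward heads → signed DEG prediction vector."""
        return self.heads(x_z)

    # ---------------------------------------------------------------- whole
    def forward(self, fingerprints: np.ndarray, similarity: np.ndarray
                ) -> tuple[Tensor, Optional[Tensor], Optional[Tensor]]:
        """Differentiable forward pass for one instance.

        Returns ``(Ŷ_G, Ŷ_P, A)`` as autodiff tensors; the latter two are
        ``None`` when the model was built without the pathway attention
        block.
        """
        x_m = self.encode_molecule(fingerprints)
        x_c = self.encode_cell(similarity)
        x_mc = self.fuse_molecule_cell(x_m, x_c)
        if self.config.use_ppab:
            x_mc_plus = self.append_pseudo_fragment(x_mc)
            x_p, A = self.ppab_forward(x_mc_plus)
            k = x_mc.shape[0]
            assoc = A[:, :k].sum(axis=1)
        else:
            x_p, A, assoc = self.pathway_table, None, None
        x_g, _ = self.pgab_forward(x_p)
        x_g_star = self.fuse_molecule_cell_gene(x_g, x_mc)
        x_z, _ = self.ggab_forward(x_g_star)
        y_hat = self.predict_gene_values(x_z)
        return y_hat, assoc, A

    def predict(self, fingerprints: np.ndarray, similarity: np.ndarray
                ) -> ForwardOutputs:
        """Non-differentiable prediction (eval mode, dropout off)."""
        was_training = self.training
        self.eval()
        try:
            y_hat, assoc, A = self.forward(fingerprints, similarity)
        finally:
            self.train(was_training)
        return ForwardOutputs(
            predicted_profile=y_hat.numpy().copy(),
            attention=None if A is None else A.numpy().copy(),
            association_scores=None if assoc is None else assoc.numpy().copy())


def badger_forward(model: Badger, molecule_smiles: str, basal_profile,
                   anchor_profiles) -> ForwardOutputs:
    """End-to-end prediction from a SMILES string and a basal expression
    profile: featurize (BRICS + Morgan, Spearman similarity) then run the
    network in eval mode."""
    from . import featurize as fz
    frag = fz.featurize_molecule(molecule_smiles, n_bits=model.config.n_bits)
    sim = fz.cell_similarity_vector("query", basal_profile, anchor_profiles)
    return model.predict(frag.fingerprints, sim.values)


# ---------------------------------------------------------------- storage

def save_checkpoint(model: Badger, path) -> None:
    """Serialize config + parameters into a single ``.npz`` file."""
    state = model.state_dict()
    np.savez(path, __config__=json.dumps(asdict(model.config)), **state)


def load_checkpoint(path) -> Badger:
    with np.load(path, allow_pickle=False) as data:
        cfg = ModelConfig(**json.loads(str(data["__config__"])))
        model = Badger(cfg)
        model.load_state_dict({k: data[k] for k in data.files
                               if k != "__config__"})
    return model
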