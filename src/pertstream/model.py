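"""The dual-stream perturbation response model.

Two streams are fused into a per-cell, per-gene expression prediction:

* **data-driven stream** — a variational autoencoder encodes a control
  cell's expression, re-samples the latent (posterior mean in eval mode)
  and decodes; only positions that were non-zero in the input are
  regenerated, zeros pass through untouched (sparsity preservation);
* **knowledge-driven stream** — learnable gene and perturbation embedding
  tables are each propagated over their graph (co-expression graph for
  genes, GO-similarity graph for perturbations) by a simplified graph
  convolution, the cell's perturbation embedding(s) are added to every gene
  position, and a pathway-masked transformer encoder refines the result.

The post-perturbation embeddings are summed over the feature axis and added
to the regenerated expression to give the prediction.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .data import PerturbDataset
from .graphs import AttentionMask
from .nn import (
    Linear,
    Module,
    Tensor,
    TransformerEncoderLayer,
    normalized_adjacency,
)

__all__ = ["ModelConfig", "DualStreamModel", "regenerate_nonzero"]


@dataclass
class ModelConfig:
    """Architecture hyperparameters (defaults follow the reference setup:
    hidden size 64 throughout, VAE latent 16 with intermediate 32, a
    512-dimensional feedforward, one graph-convolution layer per graph,
    one transformer encoder layer)."""

    hidden_dim: int = 64
    vae_latent_dim: int = 16
    vae_intermediate_dim: int = 32
    ff_dim: int = 512
    n_gnn_layers_gene: int = 1
    n_gnn_layers_pert: int = 1
    n_attention_heads: int = 4
    n_transformer_layers: int = 1
    use_vae: bool = True
    use_attention: bool = True
    use_mask: bool = True

    def __post_init__(self):
        for name in ("hidden_dim", "vae_latent_dim", "vae_intermediate_dim", "ff_dim",
                     "n_gnn_layers_gene", "n_gnn_layers_pert", "n_attention_heads",
                     "n_transformer_layers"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.hidden_dim % self.n_attention_heads != 0:
            raise ValueError("n_attention_heads must divide hidden_dim")


def regenerate_nonzero(x: np.ndarray, x_hat) -> "Tensor | np.ndarray":
    """Keep zeros of `x` exactly zero; take `x_hat` where `x` is non-zero."""
    x = np.asarray(x)
    mask = (x != 0).astype(np.float64)
    if isinstance(x_hat, Tensor):
        return x_hat * Tensor(mask)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    if x_hat.shape != x.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {x_hat.shape}")
    return x_hat * mask


class DualStreamModel(Module):
    """Dual-stream network over a fixed gene list and knowledge graphs."""

    def __init__(
        self,
        gene_names: list,
        pert_names: list,
        config: ModelConfig,
        gene_graph=None,
        pert_graph=None,
        mask: AttentionMask | None = None,
        seed: int = 0,
    ):
        self.gene_names = list(gene_names)
        self.pert_names = list(pert_names)
        self.config = config
        m, d = len(self.gene_names), config.hidden_dim
        self._gene_index = {g: i for i, g in enumerate(self.gene_names)}
        self._pert_index = {g: i for i, g in enumerate(self.pert_names)}

        rng = np.random.default_rng(seed)
        # data-driven stream: VAE
        self.enc_hidden = Linear(m, config.vae_intermediate_dim, rng)
        self.enc_mu = Linear(config.vae_intermediate_dim, config.vae_latent_dim, rng)
        self.enc_logvar = Linear(config.vae_intermediate_dim, config.vae_latent_dim, rng)
        self.dec_hidden = Linear(config.vae_latent_dim, config.vae_intermediate_dim, rng)
        self.dec_out = Linear(config.vae_intermediate_dim, m, rng)

        # knowledge-driven stream
        # standard N(0, 1) embedding-table init: keeps gene/perturbation
        # vectors well separated from the first step
        self.gene_embedding = Tensor(rng.normal(0.0, 1.0, size=(m, d)), requires_grad=True)
        self.pert_embedding = Tensor(
            rng.normal(0.0, 1.0, size=(len(self.pert_names), d)), requires_grad=True
        )
        self.gene_linear = Linear(d, d, rng)
        self.pert_linear = Linear(d, d, rng)
        self.transformer_layers = [
            TransformerEncoderLayer(d, config.n_attention_heads, config.ff_dim, rng)
            for _ in range(config.n_transformer_layers)
        ]

        self.gene_adj = self._adjacency(gene_graph, self.gene_names, self._gene_index)
        self.pert_adj = self._adjacency(pert_graph, self.pert_names, self._pert_index)
        if mask is not None and mask.matrix.shape != (m, m):
            raise ValueError(f"mask shape {mask.matrix.shape} does not match {m} genes")
        self.mask = mask

    @staticmethod
    def _adjacency(graph, names, index) -> np.ndarray:
        if graph is None:
            edges = []
        else:
            edges = [
                (u, v, data.get("weight", 1.0))
                for u, v, data in graph.edges(data=True)
                if u in index and v in index
            ]
        return normalized_adjacency(len(names), edges, index)

    # ----------------------------------------------------------- components
    def vae_encode(self, x) -> tuple[Tensor, Tensor]:
        """Encode expression (c, m) to posterior mean and sd, each (c, latent)."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if np.isnan(x).any():
            raise ValueError("NaN in expression input")
        h = self.enc_hidden(Tensor(x)).relu()
        mu = self.enc_mu(h)
        sigma = (self.enc_logvar(h) * 0.5).exp()
        return mu, sigma

    @staticmethod
    def reparameterize(mu: Tensor, sigma: Tensor, rng: np.random.Generator | None = None,
                       training: bool = True) -> Tensor:
        """z = mu + sigma * eps with eps ~ N(0, I); z = mu in eval mode."""
        if not training:
            return mu
        if rng is None:
            raise ValueError("training-mode reparameterization needs an rng")
        eps = rng.standard_normal(mu.shape)
        return mu + sigma * Tensor(eps)

    def vae_decode(self, z: Tensor) -> Tensor:
        return self.dec_out(self.dec_hidden(z).relu())

    def sgc_propagate(self, embeddings: Tensor, adjacency: np.ndarray, k_layers: int,
                      linear: Linear) -> Tensor:
        """Simplified graph convolution: k propagation steps with the
        symmetric-normalized adjacency (self-loops included), then a single
        linear map — no nonlinearity between steps."""
        h = embeddings
        a = Tensor(adjacency)
        for _ in range(k_layers):
            h = a @ h
        return linear(h)

    def combine_perturbation(self, gene_emb: Tensor, perturbations: list) -> Tensor:
        """Add each cell's (summed) perturbation embedding to every gene
        position: (m, d) gene embeddings -> (c, m, d)."""
        c = len(perturbations)
        sel = np.zeros((c, len(self.pert_names)))
        for i, pert in enumerate(perturbations):
            for gene in pert:
                if gene not in self._pert_index:
                    raise KeyError(f"no perturbation embedding for gene {gene!r}")
                sel[i, self._pert_index[gene]] = 1.0
        pert_prop = self.sgc_propagate(
            self.pert_embedding, self.pert_adj, self.config.n_gnn_layers_pert, self.pert_linear
        )
        contrib = Tensor(sel) @ pert_prop  # (c, d)
        m, d = gene_emb.shape
        return gene_emb.reshape(1, m, d) + contrib.reshape(c, 1, d)

    def masked_attention(self, post_emb: Tensor) -> Tensor:
        """Transformer encoder over the gene axis with the pathway mask."""
        m = len(self.gene_names)
        if self.config.use_mask and self.mask is not None:
            mask_matrix = self.mask.matrix
        else:
            mask_matrix = np.zeros((m, m))
        if mask_matrix.shape != (m, m):
            raise ValueError("mask/embedding size mismatch")
        h = post_emb
        for layer in self.transformer_layers:
            h = layer(h, mask_matrix)
        return h

    @staticmethod
    def collapse_and_fuse(post_emb: Tensor, regenerated) -> Tensor:
        """prediction = regenerated expression + sum of post-perturbation
        embeddings over the feature axis."""
        delta = post_emb.sum(axis=-1)
        if not isinstance(regenerated, Tensor):
            regenerated = Tensor(np.asarray(regenerated, dtype=np.float64))
        return regenerated + delta

    # -------------------------------------------------------------- forward
    def forward(
        self,
        control_expression: np.ndarray,
        perturbations: list,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, Tensor | None, Tensor | None]:
        """Predict post-perturbation expression for a batch of control cells.

        Returns (prediction (c, m), mu, sigma); mu/sigma are None when the
        VAE stream is disabled.
        """
        x = np.atleast_2d(np.asarray(control_expression, dtype=np.float64))
        if x.shape[1] != len(self.gene_names):
            raise ValueError(f"expected {len(self.gene_names)} genes, got {x.shape[1]}")
        if len(perturbations) != x.shape[0]:
            raise ValueError("one perturbation set per cell required")

        mu = sigma = None
        if self.config.use_vae:
            mu, sigma = self.vae_encode(x)
            z = self.reparameterize(mu, sigma, rng=rng, training=training)
            regenerated = regenerate_nonzero(x, self.vae_decode(z))
        else:
            regenerated = Tensor(x)

        gene_prop = self.sgc_propagate(
            self.gene_embedding, self.gene_adj, self.config.n_gnn_layers_gene, self.gene_linear
        )
        post = self.combine_perturbation(gene_prop, perturbations)
        if self.config.use_attention:
            post = self.masked_attention(post)
        prediction = self.collapse_and_fuse(post, regenerated)
        return prediction, mu, sigma

    def predict(self, control_expression: np.ndarray, perturbations: list) -> np.ndarray:
        """Deterministic eval-mode prediction as a plain array."""
        pred, _, _ = self.forward(control_expression, perturbations, training=False)
        return pred.data

    def predict_condition_mean(
        self, dataset: PerturbDataset, perturbation, max_cells: int = 100,
        seed: int = 0,
    ) -> np.ndarray:
        """Mean predicted expression under `perturbation`, averaging over
        (at most `max_cells`) control cells used as inputs."""
        ctrl = dataset.expression[dataset.control_mask()]
        if ctrl.shape[0] > max_cells:
            rng = np.random.default_rng(seed)
            ctrl = ctrl[rng.choice(ctrl.shape[0], size=max_cells, replace=False)]
        pert = frozenset(perturbation)
        preds = self.predict(ctrl, [pert] * ctrl.shape[0])
        return preds.mean(axis=0)

    # ----------------------------------------------------------- checkpoint
    def save(self, path) -> None:
        path = Path(path)
        arrays = {f"param_{i}": a for i, a in enumerate(self.state_arrays())}
        with open(path, "wb") as fh:
            np.savez(
                fh,
                __config=np.array([repr(asdict(self.config))]),
                __genes=np.array(self.gene_names),
                __perts=np.array(self.pert_names),
                __gene_adj=self.gene_adj,
                __pert_adj=self.pert_adj,
                __mask=self.mask.matrix if self.mask is not None else np.zeros(0),
                **arrays,
            )

    @classmethod
    def load(cls, path) -> "DualStreamModel":
        import ast

        with np.load(Path(path), allow_pickle=False) as npz:
            config = ModelConfig(**ast.literal_eval(str(npz["__config"][0])))
            genes = [str(g) for g in npz["__genes"]]
            perts = [str(g) for g in npz["__perts"]]
            model = cls(genes, perts, config, seed=0)
            model.gene_adj = npz["__gene_adj"]
            model.pert_adj = npz["__pert_adj"]
            mask = npz["__mask"]
            model.mask = AttentionMask(matrix=mask, gene_names=genes) if mask.size else None
            n_params = sum(1 for k in npz.files if k.startswith("param_"))
            model.load_state_arrays([npz[f"param_{i}"] for i in range(n_params)])
        return model
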