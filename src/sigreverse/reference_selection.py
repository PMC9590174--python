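"""Autoencoder embedding and surrogate-control selection.

Matched normal tissue is rarely available for brainstem tumors, so
reference controls are chosen from a healthy-tissue compendium: the
whole TPM matrix (disease samples included) is embedded with an
autoencoder, each normal sample's embedding is correlated with the
disease samples' embeddings, and the top-k most-correlated normals
become the surrogate control group.

The default training configuration — 64 encoded features, batch size
128, 100 epochs, learning rate 2e-4, with ReLU, dropout and batch
normalization between layers — matches the published pipeline this
package re-implements at desk scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._autoencoder import MLPAutoencoder
from .datatypes import ExpressionMatrix, check_finite

__all__ = [
    "AutoencoderConfig",
    "EncoderModel",
    "train_autoencoder",
    "encode",
    "select_controls",
]


@dataclass
class AutoencoderConfig:
    """Hyperparameters for the embedding autoencoder."""

    n_encoded: int = 64
    batch_size: int = 128
    epochs: int = 100
    learning_rate: float = 2e-4
    hidden_widths: list[int] = field(default_factory=lambda: [512, 128])
    dropout_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_encoded < 1:
            raise ValueError(f"n_encoded must be >= 1, got {self.n_encoded}")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.epochs < 0 or self.batch_size < 2:
            raise ValueError("epochs must be >= 0 and batch_size >= 2")


@dataclass
class EncoderModel:
    """A trained encoder plus the input transform it expects.

    The input transform is log2(TPM + 1) followed by per-gene
    standardization with the training-set mean and sd; the gene index
    is recorded so encoding refuses mismatched matrices.
    """

    network: MLPAutoencoder
    config: AutoencoderConfig
    gene_index: pd.Index
    gene_mean: np.ndarray
    gene_sd: np.ndarray
    initial_mse: float
    final_mse: float

    def prepare(self, tpm: pd.DataFrame) -> np.ndarray:
        missing = [g for g in self.gene_index if g not in tpm.index]
        if missing:
            shown = ", ".join(map(str, missing[:5]))
            raise KeyError(
                f"matrix is missing {len(missing)} training genes (first: {shown})"
            )
        x = np.log2(tpm.loc[self.gene_index].to_numpy(dtype=float).T + 1.0)
        return (x - self.gene_mean) / self.gene_sd

    def save(self, path: str | Path) -> None:
        path = Path(path)
        state = self.network.state_arrays()
        state["gene_mean"] = self.gene_mean
        state["gene_sd"] = self.gene_sd
        np.savez_compressed(path, **state)
        sidecar = {
            "config": {
                "n_encoded": self.config.n_encoded,
                "batch_size": self.config.batch_size,
                "epochs": self.config.epochs,
                "learning_rate": self.config.learning_rate,
                "hidden_widths": list(self.config.hidden_widths),
                "dropout_rate": self.config.dropout_rate,
                "seed": self.config.seed,
            },
            "gene_index": list(map(str, self.gene_index)),
            "initial_mse": self.initial_mse,
            "final_mse": self.final_mse,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "EncoderModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        config = AutoencoderConfig(**meta["config"])
        gene_index = pd.Index(meta["gene_index"], name="gene")
        with np.load(path.with_suffix(".npz") if path.suffix != ".npz" else path) as state:
            net = MLPAutoencoder(
                n_features=len(gene_index),
                n_encoded=config.n_encoded,
                hidden_widths=config.hidden_widths,
                dropout_rate=config.dropout_rate,
                seed=config.seed,
            )
            arrays = {k: state[k] for k in state.files}
            net.load_state_arrays(arrays)
            gene_mean = arrays["gene_mean"]
            gene_sd = arrays["gene_sd"]
        return cls(
            network=net,
            config=config,
            gene_index=gene_index,
            gene_mean=gene_mean,
            gene_sd=gene_sd,
            initial_mse=meta["initial_mse"],
            final_mse=meta["final_mse"],
        )


def train_autoencoder(tpm_matrix, config: AutoencoderConfig | None = None) -> EncoderModel:
    """Train the embedding autoencoder on a TPM matrix (genes x samples).

    The full matrix, disease samples included, is used for training.
    Reconstruction MSE is measured on the transformed input before and
    after training; with ``epochs=0`` the model is its initialization
    and can still encode.
    """
    if config is None:
        config = AutoencoderConfig()
    tpm = tpm_matrix.values if isinstance(tpm_matrix, ExpressionMatrix) else tpm_matrix
    check_finite(tpm, "TPM matrix")
    n_genes, n_samples = tpm.shape
    if n_samples < 2:
        raise ValueError(f"need >= 2 samples to train, got {n_samples}")
    if config.n_encoded > n_genes:
        raise ValueError(
            f"n_encoded = {config.n_encoded} exceeds the number of genes ({n_genes})"
        )

    x = np.log2(tpm.to_numpy(dtype=float).T + 1.0)  # samples x genes
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd < 1e-8, 1.0, sd)
    xs = (x - mean) / sd

    widths = [w for w in config.hidden_widths if w > 0]
    net = MLPAutoencoder(
        n_features=n_genes,
        n_encoded=config.n_encoded,
        hidden_widths=widths,
        dropout_rate=config.dropout_rate,
        seed=config.seed,
    )
    initial = net.reconstruction_mse(xs)
    net.fit(xs, epochs=config.epochs, batch_size=config.batch_size,
            learning_rate=config.learning_rate)
    final = net.reconstruction_mse(xs)
    return EncoderModel(
        network=net,
        config=config,
        gene_index=tpm.index,
        gene_mean=mean,
        gene_sd=sd,
        initial_mse=initial,
        final_mse=final,
    )


def encode(model: EncoderModel, matrix) -> pd.DataFrame:
    """Embed samples (columns of a TPM matrix) into the encoded space.

    A pure function of model and input: returns a (n_samples x
    n_encoded) DataFrame aligned to the input sample ids.  An empty
    sample set yields an empty frame with the encoded-feature header.
    """
    tpm = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    cols = [f"E{i:03d}" for i in range(model.config.n_encoded)]
    if tpm.shape[1] == 0:
        return pd.DataFrame(np.zeros((0, len(cols))), index=tpm.columns, columns=cols)
    xs = model.prepare(tpm)
    code = model.network.transform(xs)
    return pd.DataFrame(code, index=tpm.columns, columns=cols)


def _rowwise_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between every row of a and every row of b."""
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    asd = np.sqrt((az**2).sum(axis=1, keepdims=True))
    bsd = np.sqrt((bz**2).sum(axis=1, keepdims=True))
    asd[asd == 0] = np.inf  # constant embeddings correlate with nothing
    bsd[bsd == 0] = np.inf
    return (az / asd) @ (bz / bsd).T


def select_controls(
    disease_emb: pd.DataFrame,
    normal_emb: pd.DataFrame,
    k: int = 100,
    *,
    method: str = "pearson",
    aggregate: str = "median",
) -> pd.DataFrame:
    """Rank normal samples by embedding correlation with the disease cohort.

    For each normal sample the correlation with every disease sample's
    embedding is computed (Pearson by default, Spearman by flag) and
    aggregated by the median (robust to outlier disease samples).  The
    top ``k`` normals by aggregated correlation are returned,
    descending, ties broken by sample id.
    """
    if disease_emb.shape[1] != normal_emb.shape[1]:
        raise ValueError(
            f"embedding widths differ: disease {disease_emb.shape[1]} "
            f"vs normal {normal_emb.shape[1]}"
        )
    n_normals = normal_emb.shape[0]
    if k > n_normals:
        raise ValueError(f"requested k = {k} controls but only {n_normals} normals available")
    if disease_emb.shape[0] == 0:
        raise ValueError("disease embedding has no samples")

    nv = normal_emb.to_numpy(dtype=float)
    dv = disease_emb.to_numpy(dtype=float)
    if method == "spearman":
        nv = np.apply_along_axis(lambda r: pd.Series(r).rank().to_numpy(), 1, nv)
        dv = np.apply_along_axis(lambda r: pd.Series(r).rank().to_numpy(), 1, dv)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method: {method!r}")
    corr = _rowwise_correlation(nv, dv)  # normals x disease
    if aggregate == "median":
        agg = np.median(corr, axis=1)
    elif aggregate == "mean":
        agg = corr.mean(axis=1)
    else:
        raise ValueError(f"unknown aggregation: {aggregate!r}")

    table = pd.DataFrame({"sample_id": normal_emb.index, "correlation": agg})
    table = table.sort_values(
        ["correlation", "sample_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return table.head(k).reset_index(drop=True)
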