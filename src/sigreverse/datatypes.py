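"""Core in-memory containers shared across the pipeline.

Matrices are pandas DataFrames with genes on the rows and samples (or
perturbation profiles) on the columns; metadata tables are DataFrames
indexed by sample / profile / compound id.  The thin dataclasses below
mostly bundle a matrix with its metadata and record what kind of values
it holds, so downstream stages can refuse obviously wrong input (e.g.
TPM passed to a count-based test).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "DiseaseSignature",
    "ProfileLibrary",
    "SensitivityTable",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix plus per-sample metadata.

    Parameters
    ----------
    values
        DataFrame of shape (n_genes, n_samples); index = gene ids,
        columns = sample ids.
    meta
        DataFrame indexed by sample id.  Conventional columns:
        ``tissue``, ``disease`` ("normal" or a disease label),
        ``cohort`` and, when present, ``batch``.
    kind
        "counts" (nonnegative integers) or "tpm".
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    kind: Literal["counts", "tpm"] = "counts"

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.meta.index):
            if set(self.values.columns) != set(self.meta.index):
                raise ValueError(
                    "sample ids of values and meta disagree: "
                    f"{len(self.values.columns)} columns vs {len(self.meta)} meta rows"
                )
            self.meta = self.meta.loc[self.values.columns]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[:, sample_ids], self.meta.loc[sample_ids], self.kind
        )


@dataclass
class DiseaseSignature:
    """Up/down regulated gene sets with per-gene log2 fold changes.

    ``up`` and ``down`` are ordered by |log2FC| descending (ties broken
    by gene id) and are disjoint by construction.  ``provenance`` tags
    where the signature came from ("bulk", "sc", "meta", "published").
    """

    up: list[str]
    down: list[str]
    lfc: pd.Series
    provenance: str = "bulk"

    def __post_init__(self) -> None:
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ValueError(f"up/down sets overlap: {sorted(overlap)[:5]} ...")

    @property
    def genes(self) -> list[str]:
        return list(self.up) + list(self.down)

    def __len__(self) -> int:
        return len(self.up) + len(self.down)

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, "up", float(self.lfc[g])) for g in self.up]
        rows += [(g, "down", float(self.lfc[g])) for g in self.down]
        return pd.DataFrame(rows, columns=["gene", "direction", "log2fc"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: str = "published") -> "DiseaseSignature":
        required = {"gene", "direction", "log2fc"}
        if not required.issubset(frame.columns):
            raise ValueError(f"signature table needs columns {sorted(required)}")
        frame = frame.copy()
        frame["abs_lfc"] = frame["log2fc"].abs()
        frame = frame.sort_values(["abs_lfc", "gene"], ascending=[False, True])
        up = frame.loc[frame["direction"] == "up", "gene"].tolist()
        down = frame.loc[frame["direction"] == "down", "gene"].tolist()
        lfc = pd.Series(frame["log2fc"].values, index=frame["gene"].values)
        return cls(up=up, down=down, lfc=lfc, provenance=provenance)


@dataclass
class ProfileLibrary:
    """Drug-perturbation profile library over the landmark gene universe.

    ``values`` holds one differential-expression vector per profile
    (rows = profile ids, columns = landmark genes); ``meta`` is indexed
    by profile id with columns ``compound``, ``cell_line``, ``dose_um``,
    ``duration_h``.  Ground truth (planted reversal strength per
    compound) travels in ``truth`` when the library is synthetic.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    truth: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.meta.index):
            raise ValueError("profile ids of values and meta disagree")

    @property
    def landmark_genes(self) -> pd.Index:
        return self.values.columns

    @property
    def profile_ids(self) -> pd.Index:
        return self.values.index

    def ranking(self, profile_id: str) -> pd.Index:
        """Total order over the landmark universe for one profile.

        Rank 1 = most up-regulated by the drug.  Ties in the raw values
        are broken by gene id so the ranking is deterministic.
        """
        row = self.values.loc[profile_id]
        order = sorted(row.index, key=lambda g: (-row[g], g))
        return pd.Index(order)

    def to_long(self) -> pd.DataFrame:
        long = self.values.stack().rename("value").reset_index()
        long.columns = ["profile_id", "gene", "value"]
        return long.merge(self.meta.reset_index(), on="profile_id")


@dataclass
class SensitivityTable:
    """Per-(compound, cell line) AC50 records with curve-quality flags.

    ``records`` columns: compound, cell_line, ac50 (molar), cclass,
    cclass2.  Lower AC50 = more potent; cclass/cclass2 < 4 denote a
    strong, reliable dose-response signal.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"compound", "cell_line", "ac50", "cclass", "cclass2"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"sensitivity table missing columns {sorted(missing)}")
        if len(self.records) and (self.records["ac50"] <= 0).any():
            raise ValueError("AC50 values must be positive")

    def __len__(self) -> int:
        return len(self.records)


def check_finite(array: np.ndarray | pd.DataFrame, name: str) -> None:
    arr = np.asarray(array, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} contains non-finite values")
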