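"""Plain-text readers and writers for every table the pipeline exchanges.

All files are TSV (gzip-compressed when the filename ends in .gz).
Writers can prepend ``#``-prefixed provenance comment lines (config
hash, seed); readers skip them.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import pandas as pd

from .datatypes import DiseaseSignature, ExpressionMatrix, ProfileLibrary, SensitivityTable

__all__ = [
    "write_table",
    "read_table",
    "write_expression",
    "read_expression",
    "write_signature",
    "read_signature",
    "write_profile_library",
    "read_profile_library",
    "read_sensitivity",
    "read_annotations",
]


def _open_write(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "wt")
    return open(path, "w")


def write_table(
    frame: pd.DataFrame, path: str | Path, *, header_lines: list[str] | None = None,
    index: bool = False,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with _open_write(path) as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_expression(
    matrix: ExpressionMatrix, values_path: str | Path, meta_path: str | Path | None = None,
    *, header_lines: list[str] | None = None,
) -> None:
    """Genes x samples TSV (first column = gene id) plus a metadata TSV."""
    frame = matrix.values.copy()
    frame.index.name = "gene"
    write_table(frame, values_path, header_lines=header_lines, index=True)
    if meta_path is not None:
        meta = matrix.meta.copy()
        meta.index.name = "sample_id"
        write_table(meta, meta_path, header_lines=header_lines, index=True)


def read_expression(
    values_path: str | Path, meta_path: str | Path | None = None, kind: str = "counts"
) -> ExpressionMatrix:
    values = read_table(values_path, index_col=0)
    if meta_path is not None:
        meta = read_table(meta_path, index_col=0)
    else:
        meta = pd.DataFrame(index=values.columns)
    return ExpressionMatrix(values, meta, kind)


def write_signature(
    signature: DiseaseSignature, path: str | Path, *, header_lines: list[str] | None = None
) -> None:
    """Three-column signature TSV: gene, direction (up/down), log2fc."""
    write_table(signature.to_frame(), path, header_lines=header_lines)


def read_signature(path: str | Path, provenance: str = "published") -> DiseaseSignature:
    return DiseaseSignature.from_frame(read_table(path), provenance=provenance)


def write_profile_library(
    library: ProfileLibrary, path: str | Path, *, header_lines: list[str] | None = None
) -> None:
    """Long-format library TSV: profile_id, compound, cell_line, dose_um,
    duration_h, gene, value."""
    long = library.to_long()
    cols = ["profile_id", "compound", "cell_line", "dose_um", "duration_h", "gene", "value"]
    write_table(long[cols], path, header_lines=header_lines)


def read_profile_library(path: str | Path) -> ProfileLibrary:
    long = read_table(path)
    values = long.pivot(index="profile_id", columns="gene", values="value")
    meta = (
        long[["profile_id", "compound", "cell_line", "dose_um", "duration_h"]]
        .drop_duplicates("profile_id")
        .set_index("profile_id")
        .loc[values.index]
    )
    return ProfileLibrary(values=values, meta=meta)


def read_sensitivity(path: str | Path) -> SensitivityTable:
    return SensitivityTable(read_table(path))


def read_annotations(path: str | Path) -> pd.DataFrame:
    ann = read_table(path)
    if ann["compound"].duplicated().any():
        dupes = ann.loc[ann["compound"].duplicated(), "compound"].tolist()
        raise ValueError(f"duplicated compound ids in annotations: {dupes[:5]}")
    return ann.set_index("compound")
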