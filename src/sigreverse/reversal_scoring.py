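"""Reversal scoring: KS enrichment, per-profile RGES, per-compound sRGES.

The reversal gene expression score (RGES) of a drug profile against a
disease signature follows the connectivity-map lineage: genes are
ranked by the drug-induced differential expression (rank 1 = most
up-regulated by the drug), a signed Kolmogorov-Smirnov enrichment
score is computed for the disease up and down gene sets, and

    RGES = ES_up - ES_down      when the two scores differ in sign,
    RGES = 0                    when they agree in sign.

A negative RGES means the drug pushes disease-up genes to the bottom of
its ranking and disease-down genes to the top, i.e. it reverses the
disease signature.  sRGES summarizes the multiple profiles of one
compound (cell lines x doses x durations) to a single score referenced
to the 10 uM / 24 h condition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import DiseaseSignature, ProfileLibrary

__all__ = [
    "ks_enrichment",
    "ks_enrichment_positions",
    "compute_rges",
    "compute_rges_table",
    "summarize_srges",
    "reversal_threshold",
]

REFERENCE_DOSE_UM = 10.0
REFERENCE_DURATION_H = 24.0


def ks_enrichment_positions(positions: np.ndarray, n: int) -> float:
    """Signed KS enrichment from 1-based rank positions of a gene set.

    With t set members at sorted positions V(1) < ... < V(t) in a
    ranking of n genes,

        a = max_j ( j/t - V(j)/n )        (excess at the top)
        b = max_j ( V(j)/n - (j-1)/t )    (excess at the bottom)
        es = a if a > b else -b

    so es in (-1, 1]: positive when the set concentrates at the top of
    the ranking, negative at the bottom.
    """
    v = np.sort(np.asarray(positions, dtype=float))
    t = len(v)
    if t == 0:
        raise ValueError("gene set has no members in the ranking")
    if v[0] < 1 or v[-1] > n or len(np.unique(v)) != t:
        raise ValueError("positions must be distinct integers in 1..n")
    j = np.arange(1, t + 1, dtype=float)
    a = np.max(j / t - v / n)
    b = np.max(v / n - (j - 1) / t)
    return float(a) if a > b else float(-b)


def ks_enrichment(ranking: pd.Index, gene_set) -> float:
    """KS enrichment of ``gene_set`` in a ranked gene list.

    ``ranking`` is a total order over the gene universe (position 0 =
    rank 1 = most up-regulated).  Raises if the set is empty or has no
    overlap with the universe, distinguishing the two cases.
    """
    genes = list(gene_set)
    if len(genes) == 0:
        raise ValueError("gene set is empty")
    pos_of = {g: i + 1 for i, g in enumerate(ranking)}
    positions = np.array([pos_of[g] for g in genes if g in pos_of])
    if len(positions) == 0:
        raise ValueError(
            f"gene set ({len(genes)} genes) has no overlap with the ranking universe"
        )
    return ks_enrichment_positions(positions, len(ranking))


def _truncate(sig_genes: list[str], lfc: pd.Series, top_n: int) -> list[str]:
    """Keep the top_n genes by |log2FC| (ties by gene id), only if larger."""
    if top_n is None or len(sig_genes) <= top_n:
        return list(sig_genes)
    order = sorted(sig_genes, key=lambda g: (-abs(float(lfc[g])), g))
    return order[:top_n]


def compute_rges(
    ranking: pd.Index,
    signature: DiseaseSignature,
    top_n: int | None = 100,
    *,
    same_sign_zero: bool = True,
) -> tuple[float, float, float]:
    """RGES of one ranked drug profile against a disease signature.

    The up and down sets are truncated to their ``top_n`` genes by
    |log2FC| when larger, then intersected with the ranking universe.
    Returns (es_up, es_down, rges).  When only one of the two sets
    overlaps the universe the missing side contributes 0.
    """
    universe = set(ranking)
    up = [g for g in _truncate(signature.up, signature.lfc, top_n) if g in universe]
    down = [g for g in _truncate(signature.down, signature.lfc, top_n) if g in universe]
    if not up and not down:
        raise ValueError("signature has no overlap with the profile's gene universe")
    es_up = ks_enrichment(ranking, up) if up else 0.0
    es_down = ks_enrichment(ranking, down) if down else 0.0
    if same_sign_zero and es_up * es_down > 0:
        rges = 0.0
    else:
        rges = es_up - es_down
    return es_up, es_down, rges


def compute_rges_table(
    library: ProfileLibrary,
    signature: DiseaseSignature,
    top_n: int | None = 100,
    *,
    same_sign_zero: bool = True,
) -> pd.DataFrame:
    """Per-profile RGES for every profile in a library.

    Rankings are computed from the profile values (descending, ties by
    gene id).  Columns: profile_id, compound, cell_line, dose_um,
    duration_h, es_up, es_down, rges.
    """
    genes = library.landmark_genes
    # vectorized ranking: argsort on (-value, gene id)
    vals = library.values.to_numpy()
    gene_order = np.argsort(genes)  # for tie-breaks on id
    rows = []
    universe = set(genes)
    up_full = [g for g in _truncate(signature.up, signature.lfc, top_n) if g in universe]
    down_full = [g for g in _truncate(signature.down, signature.lfc, top_n) if g in universe]
    if not up_full and not down_full:
        raise ValueError("signature has no overlap with the library's landmark universe")
    gene_pos = {g: i for i, g in enumerate(genes)}
    up_idx = np.array([gene_pos[g] for g in up_full], dtype=int)
    down_idx = np.array([gene_pos[g] for g in down_full], dtype=int)
    n = len(genes)
    # ranks with deterministic tie-break: lexsort by (gene id asc) then value desc
    id_rank = np.empty(n, dtype=float)
    id_rank[gene_order] = np.arange(n)
    for i, pid in enumerate(library.profile_ids):
        order = np.lexsort((id_rank, -vals[i]))
        rank = np.empty(n, dtype=int)
        rank[order] = np.arange(1, n + 1)
        es_up = ks_enrichment_positions(rank[up_idx], n) if len(up_idx) else 0.0
        es_down = ks_enrichment_positions(rank[down_idx], n) if len(down_idx) else 0.0
        if same_sign_zero and es_up * es_down > 0:
            rges = 0.0
        else:
            rges = es_up - es_down
        m = library.meta.loc[pid]
        rows.append(
            (pid, m["compound"], m["cell_line"], m["dose_um"], m["duration_h"], es_up, es_down, rges)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "profile_id",
            "compound",
            "cell_line",
            "dose_um",
            "duration_h",
            "es_up",
            "es_down",
            "rges",
        ],
    )


def _reference_adjust(records: pd.DataFrame) -> pd.Series:
    """Adjust each profile's RGES to the 10 uM / 24 h reference condition.

    A single ordinary-least-squares fit of RGES on log10(dose/10) and
    (duration - 24), pooled over all compounds, estimates the global
    dose and duration offsets; each record's fitted offset is then
    subtracted.  Records with missing metadata contribute (and receive)
    zero offset.
    """
    rges = records["rges"].to_numpy(dtype=float)
    dose = pd.to_numeric(records.get("dose_um"), errors="coerce")
    dur = pd.to_numeric(records.get("duration_h"), errors="coerce")
    x1 = np.log10(dose / REFERENCE_DOSE_UM).fillna(0.0).to_numpy()
    x2 = ((dur - REFERENCE_DURATION_H) / REFERENCE_DURATION_H).fillna(0.0).to_numpy()
    X = np.column_stack([np.ones_like(rges), x1, x2])
    if len(records) >= 3 and (np.ptp(x1) > 0 or np.ptp(x2) > 0):
        beta, *_ = np.linalg.lstsq(X, rges, rcond=None)
    else:
        beta = np.zeros(3)
    offset = x1 * beta[1] + x2 * beta[2]
    return pd.Series(rges - offset, index=records.index)


def summarize_srges(
    records: pd.DataFrame,
    *,
    reference_adjust: bool = True,
) -> pd.DataFrame:
    """Summarize per-profile RGES records into one sRGES per compound.

    Per compound: (1) each RGES is adjusted to the 10 uM / 24 h
    reference by globally fitted additive dose/duration offsets (or
    left as-is with ``reference_adjust=False``), (2) adjusted values
    are averaged within cell line, (3) sRGES is the mean over cell
    lines.  The table is sorted ascending (most reversing first), ties
    broken by compound id.
    """
    if len(records) == 0:
        raise ValueError("no RGES records to summarize")
    if records["compound"].isna().any():
        raise ValueError("every RGES record needs a compound id")
    rec = records.copy()
    rec["adj_rges"] = _reference_adjust(rec) if reference_adjust else rec["rges"]
    per_line = (
        rec.groupby(["compound", "cell_line"], sort=True)["adj_rges"].mean().reset_index()
    )
    srges = per_line.groupby("compound", sort=True)["adj_rges"].mean().rename("srges")
    n_profiles = rec.groupby("compound")["rges"].size().rename("n_profiles")
    n_lines = per_line.groupby("compound")["cell_line"].nunique().rename("n_cell_lines")
    out = pd.concat([srges, n_profiles, n_lines], axis=1).reset_index()
    out = out.sort_values(["srges", "compound"], kind="mergesort").reset_index(drop=True)
    return out


def reversal_threshold(srges_table: pd.DataFrame, cutoff: float = -0.1) -> pd.DataFrame:
    """Rows with sRGES strictly below the cutoff, order preserved.

    The default -0.1 is the conventional threshold for compounds that
    effectively reverse the disease signature.
    """
    return srges_table.loc[srges_table["srges"] < cutoff].reset_index(drop=True)
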