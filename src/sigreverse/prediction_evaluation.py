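"""Evaluation of reversal predictions against experimental drug sensitivity.

Covers the downstream half of the pipeline: curve-quality filtering of
the AC50 screen, correlation of per-compound sRGES with log10 AC50,
permutation enrichment of drug target/MOA classes in the ranked
predictions, the final hit filter (reversal cutoff, MOA exclusions,
minimum profile count, clinical phase), and a reversal check of new
treatment RNA-seq against the disease signature.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import DiseaseSignature, SensitivityTable
from .reversal_scoring import ks_enrichment_positions

logger = logging.getLogger(__name__)

__all__ = [
    "filter_sensitivity",
    "correlate_efficacy",
    "target_class_enrichment",
    "filter_hits",
    "reversal_check",
    "DEFAULT_EXCLUDED_MOAS",
]

DEFAULT_EXCLUDED_MOAS = frozenset(
    {"top inhibitor", "cdk inhibitor", "hdac inhibitor", "dna inhibitor"}
)


def filter_sensitivity(sensitivity: SensitivityTable, max_cclass: int = 4) -> SensitivityTable:
    """Keep records with strong dose-response signal.

    Both curve-quality flags must be strictly below ``max_cclass``
    (default 4), mirroring the screening dataset's quality convention.
    """
    rec = sensitivity.records
    keep = (rec["cclass"] < max_cclass) & (rec["cclass2"] < max_cclass)
    return SensitivityTable(rec.loc[keep].reset_index(drop=True))


def correlate_efficacy(
    srges_table: pd.DataFrame,
    sensitivity: SensitivityTable,
    srges_cutoff: float | None = -0.1,
) -> tuple[float, float, int]:
    """Pearson correlation between sRGES and log10 AC50 over compounds.

    AC50 is summarized per compound as the median over cell lines and
    log10-transformed.  By default only compounds passing the sRGES
    cutoff enter the correlation (pass ``srges_cutoff=None`` for all
    overlapping compounds).  Returns (r, two-sided p from the t
    distribution, n); raises when fewer than 3 compounds remain.
    """
    ac50 = sensitivity.records.groupby("compound")["ac50"].median()
    table = srges_table
    if srges_cutoff is not None:
        table = table.loc[table["srges"] < srges_cutoff]
    merged = table.merge(np.log10(ac50).rename("log10_ac50"), on="compound")
    n = len(merged)
    if n < 3:
        raise ValueError(
            f"only {n} compounds overlap between predictions and sensitivity (need >= 3)"
        )
    r, p = stats.pearsonr(merged["srges"], merged["log10_ac50"])
    return float(r), float(p), n


def target_class_enrichment(
    srges_table: pd.DataFrame,
    annotations: pd.DataFrame,
    n_perm: int = 1000,
    *,
    class_column: str = "moa_class",
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation enrichment of each target/MOA class in the ranking.

    Compounds are ranked by sRGES ascending (most reversing = rank 1);
    each class with >= 2 members present gets a KS enrichment score in
    that ranking and a one-sided permutation p-value — the fraction of
    ``n_perm`` random same-size compound sets with es >= observed, with
    the +1 correction on numerator and denominator so p is never 0.
    Classes with < 2 members (or all members) are skipped and logged.
    """
    ranked = srges_table.sort_values(["srges", "compound"], kind="mergesort")
    compounds = ranked["compound"].tolist()
    pos_of = {c: i + 1 for i, c in enumerate(compounds)}
    n = len(compounds)
    ann = annotations.reindex(compounds)
    rng = np.random.default_rng(seed)

    rows = []
    for cls, members in ann.groupby(class_column).groups.items():
        positions = np.array([pos_of[c] for c in members])
        t = len(positions)
        if t < 2 or t >= n:
            logger.info("skipping class %r with %d ranked members", cls, t)
            continue
        es = ks_enrichment_positions(positions, n)
        null = np.empty(n_perm)
        for b in range(n_perm):
            null[b] = ks_enrichment_positions(
                rng.choice(n, size=t, replace=False) + 1, n
            )
        p = (1 + int(np.sum(null >= es))) / (n_perm + 1)
        rows.append((cls, t, es, p))
    return pd.DataFrame(rows, columns=["class", "n_members", "es", "p"]).sort_values(
        "p", kind="mergesort", ignore_index=True
    )


def filter_hits(
    srges_table: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    *,
    srges_cutoff: float = -0.1,
    exclude_moa: set[str] | frozenset[str] = DEFAULT_EXCLUDED_MOAS,
    min_profiles: int = 3,
    exclude_preclinical: bool = False,
) -> pd.DataFrame:
    """Final hit table after the reversal and confidence filters.

    Drops compounds with sRGES >= cutoff, an excluded MOA class
    (matched case-insensitively), fewer than ``min_profiles`` profiles,
    or — when the flag is set — a "Preclinical" clinical phase.
    Compounds absent from the annotation table are kept and logged.
    Output is sorted by sRGES ascending.
    """
    exclude = {m.lower() for m in exclude_moa}
    table = srges_table.loc[srges_table["srges"] < srges_cutoff].copy()
    table = table.loc[table["n_profiles"] >= min_profiles]
    if annotations is not None:
        ann = annotations.reindex(table["compound"])
        unannotated = ann.index[ann.isna().all(axis=1)]
        if len(unannotated):
            logger.info("keeping %d unannotated compounds", len(unannotated))
        moa = ann["moa_class"].fillna("").str.lower().to_numpy()
        keep = ~np.isin(moa, list(exclude))
        if exclude_preclinical:
            phase = ann["clinical_phase"].fillna("").str.lower().to_numpy()
            keep &= phase != "preclinical"
        table = table.loc[keep]
        table = table.merge(annotations, left_on="compound", right_index=True, how="left")
    return table.sort_values(["srges", "compound"], kind="mergesort", ignore_index=True)


def reversal_check(
    treatment_de: pd.DataFrame,
    signature: DiseaseSignature,
    n_perm: int = 1000,
    *,
    top_n: int | None = None,
    seed: int = 0,
) -> tuple[float, float]:
    """Does a drug-vs-vehicle DE profile reverse the disease signature?

    Genes are ranked by treatment log2FC descending and the statistic
    is ES(up set) - ES(down set) in that ranking — the same enrichment
    math as the profile-level reversal score.  The p-value is a
    one-sided (toward negative, i.e. reversal) permutation test over
    random gene sets of the same sizes, with the +1 correction.
    Requires the treatment DE to cover at least half of the signature
    genes.
    """
    sig_genes = set(signature.genes)
    covered = sig_genes & set(treatment_de.index)
    coverage = len(covered) / max(len(sig_genes), 1)
    if coverage < 0.5:
        raise ValueError(
            f"treatment DE covers only {coverage:.0%} of signature genes (need >= 50%)"
        )
    order = treatment_de.sort_values(
        "log2fc", ascending=False, kind="mergesort"
    ).index
    pos_of = {g: i + 1 for i, g in enumerate(order)}
    n = len(order)
    up_pos = np.array([pos_of[g] for g in signature.up if g in pos_of])
    down_pos = np.array([pos_of[g] for g in signature.down if g in pos_of])

    def _stat(up, down):
        es_up = ks_enrichment_positions(up, n) if len(up) else 0.0
        es_down = ks_enrichment_positions(down, n) if len(down) else 0.0
        return es_up - es_down

    observed = _stat(up_pos, down_pos)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    t_up, t_down = len(up_pos), len(down_pos)
    for b in range(n_perm):
        perm = rng.choice(n, size=t_up + t_down, replace=False) + 1
        null[b] = _stat(perm[:t_up], perm[t_up:])
    p = (1 + int(np.sum(null <= observed))) / (n_perm + 1)
    return float(observed), float(p)
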