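"""Disease-signature construction from bulk and single-cell expression.

The bulk route mirrors the standard count-based workflow: trimmed-mean
(TMM) library-size normalization, removal of weakly expressed genes, a
negative-binomial GLM per gene with trend-shrunk tagwise dispersion,
Wald tests against a t reference, and Benjamini-Hochberg adjustment.
Unwanted variation (residual batch structure across cohorts) is
estimated by factor analysis on negative-control genes — the genes
least associated with the case/control contrast — and regressed out or
supplied to the GLM as covariates.

The single-cell route applies an equal-variance Student t-test to
log(RSEM + 0.1) values after dropping low-variance genes.

Signatures are thresholded at |log2FC| > 1 and adjusted p < 0.05 by
default and can be combined into a meta-signature.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .datatypes import DiseaseSignature, ExpressionMatrix, ProfileLibrary, SensitivityTable

logger = logging.getLogger(__name__)

__all__ = [
    "select_empirical_controls",
    "remove_unwanted_variation",
    "tmm_norm_factors",
    "bh_adjust",
    "compute_de",
    "threshold_signature",
    "sc_de_table",
    "sc_signature",
    "combine_signatures",
    "evaluate_signature",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to [0, 1]."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def _values(x) -> pd.DataFrame:
    return x.values if isinstance(x, ExpressionMatrix) else x


def _check_counts(frame: pd.DataFrame, name: str) -> np.ndarray:
    arr = frame.to_numpy()
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} contains non-finite values")
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValueError(
            f"{name} must hold nonnegative integer counts; "
            "a TPM/normalized matrix may have been passed by mistake"
        )
    return np.round(arr).astype(np.int64)


# ---------------------------------------------------------------------------
# empirical controls + unwanted variation


def select_empirical_controls(counts_case, counts_control, n: int = 5000) -> list[str]:
    """Genes least associated with the case/control contrast.

    A first-pass Welch t-test on log2 counts-per-million ranks genes by
    evidence of differential expression; the ``n`` genes with the
    largest p-values are returned as empirical negative controls for
    unwanted-variation estimation.  Ties are broken by gene id.
    """
    case = _values(counts_case)
    ctrl = _values(counts_control)
    if not case.index.equals(ctrl.index):
        raise ValueError("case and control matrices must share a gene index")
    if n > len(case.index):
        raise ValueError(f"requested {n} control genes but only {len(case.index)} genes exist")
    logcpm = _log_cpm(pd.concat([case, ctrl], axis=1))
    a = logcpm.iloc[:, : case.shape[1]].to_numpy()
    b = logcpm.iloc[:, case.shape[1] :].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)  # constant genes carry no contrast signal
    order = sorted(range(len(p)), key=lambda i: (-p[i], case.index[i]))
    return [case.index[i] for i in order[:n]]


def _log_cpm(counts: pd.DataFrame, prior: float = 0.5) -> pd.DataFrame:
    lib = counts.sum(axis=0).replace(0, 1)
    return np.log2(counts.add(prior).div(lib + 1.0, axis=1) * 1e6)


def remove_unwanted_variation(
    counts,
    control_genes,
    k_factors: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimate and regress out unwanted-variation factors.

    Counts are transformed to log2 counts-per-million (so library size
    does not masquerade as a factor) and centered gene-wise; the top
    ``k_factors`` left singular vectors of the (samples x control
    genes) block give the factor matrix W, whose contribution is then
    removed from every gene by ordinary least squares.
    ``k_factors = 0`` returns the centered log matrix unchanged.
    Returns (adjusted matrix, W).
    """
    frame = _values(counts)
    if k_factors < 0:
        raise ValueError(f"k_factors must be nonnegative, got {k_factors}")
    if k_factors > frame.shape[1] - 1:
        raise ValueError(
            f"k_factors = {k_factors} exceeds n_samples - 1 = {frame.shape[1] - 1}"
        )
    missing = [g for g in control_genes if g not in frame.index]
    if missing:
        raise KeyError(f"control gene not in matrix: {missing[0]!r}")

    logx = _log_cpm(frame)
    centered = logx.sub(logx.mean(axis=1), axis=0)
    W = pd.DataFrame(index=frame.columns)
    if k_factors == 0:
        return centered, W

    block = centered.loc[list(control_genes)].to_numpy().T  # samples x controls
    u, s, _ = np.linalg.svd(block, full_matrices=False)
    k = min(k_factors, len(s))
    scores = u[:, :k] * s[:k]
    scores[:, s[:k] < 1e-10] = 0.0  # constant controls carry no factor
    W = pd.DataFrame(scores, index=frame.columns, columns=[f"W{i+1}" for i in range(k)])

    wmat = W.to_numpy()
    if np.allclose(wmat, 0):
        return centered, W
    alpha, *_ = np.linalg.lstsq(wmat, centered.to_numpy().T, rcond=None)
    adjusted = centered.to_numpy() - (wmat @ alpha).T
    return pd.DataFrame(adjusted, index=frame.index, columns=frame.columns), W


# ---------------------------------------------------------------------------
# TMM normalization


def tmm_norm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors, geometric mean 1."""
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    cpm_q75 = np.quantile(mat / lib, 0.75, axis=0)
    ref_pos = int(np.argmin(np.abs(cpm_q75 - cpm_q75.mean())))
    y_r = mat[:, ref_pos]
    n_r = y_r.sum()
    factors = []
    for j in range(mat.shape[1]):
        y_s = mat[:, j]
        n_s = y_s.sum()
        keep = (y_s > 0) & (y_r > 0)
        if keep.sum() < 10:
            factors.append(1.0)
            continue
        ys, yr = y_s[keep], y_r[keep]
        m = np.log2((ys / n_s) / (yr / n_r))
        a = 0.5 * np.log2((ys / n_s) * (yr / n_r))
        w = (n_s - ys) / (n_s * ys) + (n_r - yr) / (n_r * yr)
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        mask = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if mask.sum() == 0 or w[mask].sum() == 0:
            factors.append(1.0)
        else:
            factors.append(2.0 ** (np.sum(m[mask] / w[mask]) / np.sum(1.0 / w[mask])))
    f = np.asarray(factors)
    f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=counts.columns)


# ---------------------------------------------------------------------------
# NB GLM differential expression


def _irls_nb(Y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi: np.ndarray, n_iter: int = 25):
    """Vectorized IRLS for per-gene NB GLMs sharing one design matrix.

    Y: genes x samples; X: samples x p; offset: samples; phi: genes.
    Returns (beta genes x p, mu genes x samples, cov genes x p x p).
    """
    G, n = Y.shape
    p = X.shape[1]
    z0 = np.log(Y + 0.5) - offset[None, :]
    beta = z0 @ np.linalg.pinv(X).T
    for _ in range(n_iter):
        eta = beta @ X.T + offset[None, :]
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        w = mu / (1.0 + phi[:, None] * mu)
        z = (eta - offset[None, :]) + (Y - mu) / mu
        XtWX = np.einsum("np,gn,nq->gpq", X, w, X)
        XtWz = np.einsum("np,gn,gn->gp", X, w, z)
        XtWX += 1e-8 * np.eye(p)[None, :, :]
        new_beta = np.linalg.solve(XtWX, XtWz[:, :, None])[:, :, 0]
        delta = np.max(np.abs(new_beta - beta))
        beta = new_beta
        if delta < 1e-8:
            break
    eta = np.clip(beta @ X.T + offset[None, :], -30, 30)
    mu = np.exp(eta)
    w = mu / (1.0 + phi[:, None] * mu)
    XtWX = np.einsum("np,gn,nq->gpq", X, w, X) + 1e-8 * np.eye(p)[None, :, :]
    cov = np.linalg.inv(XtWX)
    return beta, mu, cov


def _estimate_dispersion(
    Y: np.ndarray, mu: np.ndarray, p: int, prior_df: float = 20.0
) -> np.ndarray:
    """Method-of-moments tagwise dispersion shrunk toward a mean trend."""
    n = Y.shape[1]
    resid_df = max(n - p, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.sum(((Y - mu) ** 2 - mu) / mu**2, axis=1) / resid_df
    raw = np.clip(np.where(np.isfinite(raw), raw, 0.0), 1e-6, 10.0)
    log_mean = np.log(mu.mean(axis=1) + 1e-8)
    if len(raw) >= 50:
        trend = lowess(raw, log_mean, frac=0.5, return_sorted=False)
        trend = np.clip(np.where(np.isfinite(trend), trend, np.median(raw)), 1e-6, 10.0)
    else:
        trend = np.full_like(raw, np.median(raw))
    shrunk = (resid_df * raw + prior_df * trend) / (resid_df + prior_df)
    return np.clip(shrunk, 1e-6, 10.0)


def compute_de(
    counts_case,
    counts_control,
    covariates: pd.DataFrame | None = None,
    min_cpm: float = 1.0,
    min_samples: int | None = None,
    dispersion_prior_df: float = 20.0,
) -> pd.DataFrame:
    """Per-gene negative-binomial differential expression, case vs control.

    Library sizes are scaled by TMM factors; genes below ``min_cpm``
    counts-per-million in fewer than ``min_samples`` samples (default:
    the smaller group size) are removed before testing.  Each remaining
    gene gets an NB GLM (log link, offsets = log effective library
    size) with design [intercept, group, covariates...]; dispersion is
    a method-of-moments tagwise estimate shrunk toward a lowess mean
    trend; the group coefficient's Wald statistic is referred to a t
    distribution with residual degrees of freedom; p-values are BH
    adjusted over the tested genes.

    Returns a DataFrame indexed by gene with columns log2fc, p, padj,
    mean_expr (average log2 CPM).
    """
    case = _values(counts_case)
    ctrl = _values(counts_control)
    if not case.index.equals(ctrl.index):
        raise ValueError("case and control matrices must share a gene index")
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError(
            f"need >= 2 samples per group, got {case.shape[1]} case / {ctrl.shape[1]} control"
        )
    Yc = _check_counts(case, "case counts")
    Yn = _check_counts(ctrl, "control counts")
    # positional internal sample names: the two groups may reuse ids
    sample_names = [f"case_{c}" for c in case.columns] + [f"ctrl_{c}" for c in ctrl.columns]
    counts = pd.DataFrame(np.hstack([Yc, Yn]), index=case.index, columns=sample_names)
    group = np.r_[np.ones(case.shape[1]), np.zeros(ctrl.shape[1])]

    lib = counts.sum(axis=0).to_numpy(dtype=float)
    norm = tmm_norm_factors(counts).to_numpy()
    eff_lib = lib * norm
    offset = np.log(eff_lib)

    if min_samples is None:
        min_samples = min(case.shape[1], ctrl.shape[1])
    cpm = counts.to_numpy() / eff_lib[None, :] * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    if keep.sum() == 0:
        raise ValueError("no genes pass the weak-expression filter")
    Y = counts.to_numpy(dtype=float)[keep]
    genes = counts.index[keep]

    X = np.column_stack([np.ones_like(group), group])
    if covariates is not None and covariates.shape[1] > 0:
        orig_columns = list(case.columns) + list(ctrl.columns)
        if len(set(orig_columns)) == len(orig_columns):
            cov = covariates.reindex(orig_columns)
        elif len(covariates) == len(orig_columns):
            cov = covariates  # ambiguous ids: rows taken in sample order
        else:
            raise ValueError("covariates cannot be aligned to duplicated sample ids")
        if cov.isna().any().any():
            raise ValueError("covariates missing for some samples")
        cmat = cov.to_numpy(dtype=float)
        cmat = cmat - cmat.mean(axis=0)
        sd = cmat.std(axis=0)
        sd[sd == 0] = 1.0
        X = np.column_stack([X, cmat / sd])
    p_params = X.shape[1]
    if counts.shape[1] <= p_params:
        raise ValueError("more model parameters than samples")

    # pass 1: Poisson-like fit to get means for dispersion estimation
    phi0 = np.full(Y.shape[0], 1e-6)
    _, mu0, _ = _irls_nb(Y, X, offset, phi0, n_iter=8)
    phi = _estimate_dispersion(Y, mu0, p_params, prior_df=dispersion_prior_df)
    # pass 2: NB fit at the shrunk dispersions
    beta, mu, cov_b = _irls_nb(Y, X, offset, phi)

    se = np.sqrt(np.maximum(cov_b[:, 1, 1], 1e-30))
    tstat = beta[:, 1] / se
    df_resid = Y.shape[1] - p_params
    pval = 2.0 * stats.t.sf(np.abs(tstat), df=df_resid)
    padj = bh_adjust(pval)
    padj = np.maximum(padj, pval)  # BH step-up never below the raw p

    log2fc = beta[:, 1] / np.log(2.0)
    mean_expr = np.log2(cpm[keep].mean(axis=1) + 0.5)
    return pd.DataFrame(
        {"log2fc": log2fc, "p": pval, "padj": padj, "mean_expr": mean_expr},
        index=genes,
    )


# ---------------------------------------------------------------------------
# thresholding, single cell, combination


def threshold_signature(
    de: pd.DataFrame,
    lfc_min: float = 1.0,
    padj_max: float = 0.05,
    provenance: str = "bulk",
) -> DiseaseSignature:
    """Apply the |log2FC| > lfc_min, padj < padj_max thresholds.

    Gene lists are ordered by |log2FC| descending, ties by gene id.  An
    empty signature is permitted (and logged), e.g. for a null
    contrast.
    """
    up_mask = (de["log2fc"] > lfc_min) & (de["padj"] < padj_max)
    down_mask = (de["log2fc"] < -lfc_min) & (de["padj"] < padj_max)

    def _ordered(mask):
        sub = de.loc[mask]
        return sorted(sub.index, key=lambda g: (-abs(float(sub.loc[g, "log2fc"])), g))

    up, down = _ordered(up_mask), _ordered(down_mask)
    if not up and not down:
        logger.warning("thresholding produced an empty signature")
    lfc = de.loc[up + down, "log2fc"]
    return DiseaseSignature(up=up, down=down, lfc=lfc, provenance=provenance)


def sc_de_table(
    values: pd.DataFrame,
    labels: pd.Series | pd.DataFrame,
    var_min: float = 0.1,
    malignant_label: str = "malignant",
    control_label: str = "oligodendrocyte",
) -> pd.DataFrame:
    """Per-gene malignant-vs-oligodendrocyte t-tests on log(RSEM + 0.1).

    Genes whose variance across all cells is below ``var_min`` are
    removed before testing; each remaining gene gets an equal-variance
    two-sample Student t-test, with log2FC the mean natural-log
    difference divided by ln 2, and BH adjustment over tested genes.
    Returns a DataFrame indexed by gene with columns t, log2fc, p,
    padj, mean_expr.
    """
    if isinstance(labels, pd.DataFrame):
        labels = labels["cell_type"]
    labels = labels.reindex(values.columns)
    mal = values.loc[:, (labels == malignant_label).to_numpy()]
    oligo = values.loc[:, (labels == control_label).to_numpy()]
    for name, block in (("malignant", mal), ("control", oligo)):
        if block.shape[1] < 2:
            raise ValueError(f"{name} group has {block.shape[1]} cells (< 2)")

    logx = np.log(pd.concat([mal, oligo], axis=1).astype(float) + 0.1)
    variances = logx.var(axis=1, ddof=1)
    logx = logx.loc[variances >= var_min]
    a = logx.iloc[:, : mal.shape[1]].to_numpy()
    b = logx.iloc[:, mal.shape[1] :].to_numpy()
    tstat, pval = stats.ttest_ind(a, b, axis=1, equal_var=True)
    pval = np.where(np.isfinite(pval), pval, 1.0)
    tstat = np.where(np.isfinite(tstat), tstat, 0.0)
    lfc = (a.mean(axis=1) - b.mean(axis=1)) / np.log(2.0)
    return pd.DataFrame(
        {
            "t": tstat,
            "log2fc": lfc,
            "p": pval,
            "padj": bh_adjust(pval),
            "mean_expr": logx.mean(axis=1),
        },
        index=logx.index,
    )


def sc_signature(
    values: pd.DataFrame,
    labels: pd.Series | pd.DataFrame,
    var_min: float = 0.1,
    lfc_min: float = 1.0,
    padj_max: float = 0.05,
    malignant_label: str = "malignant",
    control_label: str = "oligodendrocyte",
) -> DiseaseSignature:
    """Single-cell disease signature: malignant vs oligodendrocyte cells.

    Thresholds the :func:`sc_de_table` result at |log2FC| > lfc_min and
    adjusted p < padj_max.
    """
    de = sc_de_table(
        values, labels, var_min=var_min,
        malignant_label=malignant_label, control_label=control_label,
    )
    return threshold_signature(de, lfc_min=lfc_min, padj_max=padj_max, provenance="sc")


def combine_signatures(
    sig_a: DiseaseSignature,
    sig_b: DiseaseSignature,
    rule: str = "intersection",
    lfc_min: float = 1.0,
) -> DiseaseSignature:
    """Combine two signatures into a meta-signature.

    Rules: "intersection" (direction-consistent intersection with
    averaged log2FC, the default), "union" (direction-consistent
    union), "average" (average log2FC over the union, then re-threshold
    at ``lfc_min``).  Genes with conflicting directions are excluded
    and logged under every rule.
    """
    up_a, up_b = set(sig_a.up), set(sig_b.up)
    down_a, down_b = set(sig_a.down), set(sig_b.down)
    conflicts = (up_a & down_b) | (down_a & up_b)
    if conflicts:
        logger.info("excluding %d direction-conflicting genes", len(conflicts))

    def _mean_lfc(g):
        vals = [s.lfc[g] for s in (sig_a, sig_b) if g in s.lfc.index]
        return float(np.mean(vals))

    if rule == "intersection":
        up = (up_a & up_b) - conflicts
        down = (down_a & down_b) - conflicts
    elif rule == "union":
        up = (up_a | up_b) - conflicts
        down = (down_a | down_b) - conflicts
    elif rule == "average":
        pool = (up_a | up_b | down_a | down_b) - conflicts
        up = {g for g in pool if _mean_lfc(g) > lfc_min}
        down = {g for g in pool if _mean_lfc(g) < -lfc_min}
    else:
        raise ValueError(f"unknown combination rule: {rule!r}")

    lfc = pd.Series({g: _mean_lfc(g) for g in up | down}, dtype=float)
    order = lambda gs: sorted(gs, key=lambda g: (-abs(lfc[g]), g))  # noqa: E731
    return DiseaseSignature(up=order(up), down=order(down), lfc=lfc, provenance="meta")


def evaluate_signature(
    signature: DiseaseSignature,
    library: ProfileLibrary,
    sensitivity: SensitivityTable,
    top_n: int = 100,
    srges_cutoff: float = -0.1,
    max_cclass: int = 4,
) -> tuple[float, float, int]:
    """End-to-end evaluation of one signature: sRGES vs AC50 correlation.

    Scores every profile in the library against the signature,
    summarizes to per-compound sRGES, filters the sensitivity records
    by curve quality, and returns the Pearson correlation triple
    (r, p, n) between sRGES and log10 median AC50 over compounds
    passing the sRGES cutoff.  Used to rank alternative signatures,
    including published ones read from TSV.
    """
    from .prediction_evaluation import correlate_efficacy, filter_sensitivity
    from .reversal_scoring import compute_rges_table, summarize_srges

    if len(signature) == 0:
        raise ValueError("signature is empty")
    if len(sensitivity) == 0:
        raise ValueError("sensitivity table is empty")
    records = compute_rges_table(library, signature, top_n=top_n)
    srges = summarize_srges(records)
    filtered = filter_sensitivity(sensitivity, max_cclass=max_cclass)
    return correlate_efficacy(srges, filtered, srges_cutoff=srges_cutoff)
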