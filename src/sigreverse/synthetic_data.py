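"""Synthetic data generators for every input the pipeline consumes.

The generators emulate the statistical structure of the real inputs —
a bulk RNA-seq compendium of healthy tissues with an optional batch
factor, a disease cohort carrying a planted up/down signature, a
drug-perturbation profile library with planted reversal strengths, a
drug-sensitivity screen whose AC50s are monotone in reversal strength,
and a single-cell RSEM-style matrix with dropout — so the whole
analysis can be exercised and validated without any external download.

Every generator is deterministic under its seed and returns its ground
truth (tissue mean profiles, batch loadings, planted gene sets, per-
compound reversal strength theta) alongside the data.

Counts are negative-binomial with a mean/dispersion parameterization,
variance = mu + phi * mu^2 (phi default 0.1, a typical bulk RNA-seq
overdispersion).  Gene lengths are fixed at 1 kb by default so TPM is
proportional to count / library size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, ProfileLibrary, SensitivityTable

__all__ = [
    "CompendiumSpec",
    "PlantedSignature",
    "PlantedCompound",
    "Compendium",
    "generate_compendium",
    "generate_disease_cohort",
    "generate_drug_library",
    "generate_sensitivity",
    "generate_sc_matrix",
    "random_planted_signature",
    "default_compound_panel",
    "annotations_from_panel",
    "tpm_from_counts",
]

DEFAULT_CELL_LINES = ("SU-DIPG-IV", "JHH-DIPG-1", "SU-DIPG-XIII", "SU-DIPG-VI")
DEFAULT_PROGRAMS = ("Cell cycle", "OPC like", "AC like", "OC like")
REFERENCE_DOSE_UM = 10.0
REFERENCE_DURATION_H = 24.0


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _gene_index(n_genes: int) -> pd.Index:
    width = max(5, len(str(n_genes)))
    return pd.Index([f"G{i:0{width}d}" for i in range(n_genes)], name="gene")


# ---------------------------------------------------------------------------
# specs


@dataclass
class CompendiumSpec:
    """Configuration of the synthetic healthy-tissue compendium.

    ``tissues`` lists (tissue name, n_samples) pairs; the disease
    cohort is later drawn from the ``source_tissue`` model.  Defaults
    mirror the scale of the emulated study: a 978-landmark-gene
    universe and a 22-sample disease cohort.
    """

    n_genes: int = 2000
    n_landmark: int = 978
    tissues: list[tuple[str, int]] = field(
        default_factory=lambda: [("brain", 200), ("liver", 150), ("muscle", 150)]
    )
    n_disease_samples: int = 22
    source_tissue: str = "brain"
    nb_dispersion: float = 0.1
    library_size_range: tuple[float, float] = (1e6, 3e6)
    batch_strength: float = 0.0
    batch_gene_fraction: float = 0.1
    tissue_effect_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError(f"invalid CompendiumSpec.n_genes: {self.n_genes}")
        if not (0 < self.n_landmark <= self.n_genes):
            raise ValueError(
                f"invalid CompendiumSpec.n_landmark: {self.n_landmark} "
                f"(n_genes = {self.n_genes})"
            )
        names = [t for t, _ in self.tissues]
        if len(set(names)) != len(names):
            raise ValueError("invalid CompendiumSpec.tissues: duplicate tissue names")
        for t, n in self.tissues:
            if n < 2:
                raise ValueError(
                    f"invalid CompendiumSpec.tissues: tissue {t!r} has {n} samples (< 2)"
                )
        if self.source_tissue not in names:
            raise ValueError(
                f"invalid CompendiumSpec.source_tissue: {self.source_tissue!r} not in tissues"
            )
        if self.n_disease_samples < 0:
            raise ValueError(
                f"invalid CompendiumSpec.n_disease_samples: {self.n_disease_samples}"
            )
        if self.nb_dispersion < 0:
            raise ValueError(f"invalid CompendiumSpec.nb_dispersion: {self.nb_dispersion}")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError(
                f"invalid CompendiumSpec.library_size_range: {self.library_size_range}"
            )
        if self.batch_strength < 0:
            raise ValueError(f"invalid CompendiumSpec.batch_strength: {self.batch_strength}")


@dataclass
class PlantedSignature:
    """Ground-truth disease signature planted into the cohort.

    ``effect_log2fc`` is signed per gene: positive on ``up_genes``
    (disease-elevated), negative on ``down_genes``.  ``control_genes``
    are guaranteed unaffected and serve as negative controls for
    unwanted-variation estimation.
    """

    up_genes: list[str]
    down_genes: list[str]
    effect_log2fc: pd.Series
    control_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        up, down, ctrl = set(self.up_genes), set(self.down_genes), set(self.control_genes)
        if up & down:
            raise ValueError("planted up and down gene sets overlap")
        if ctrl & (up | down):
            raise ValueError("planted control genes overlap the signature")
        missing = (up | down) - set(self.effect_log2fc.index)
        if missing:
            raise ValueError(f"effect_log2fc missing genes: {sorted(missing)[:5]}")

    @property
    def genes(self) -> list[str]:
        return list(self.up_genes) + list(self.down_genes)


@dataclass
class PlantedCompound:
    """A synthetic compound with ground-truth reversal strength.

    ``theta`` in [0, 1] scales how strongly the compound's profiles
    oppose the planted disease signature; 0 = pure noise, 1 = full
    reversal at the 10 uM / 24 h reference condition.
    """

    compound: str
    theta: float
    moa_class: str = "null"
    clinical_phase: str = "Launched"
    conditions: list[tuple[str, float, float]] = field(
        default_factory=lambda: [(DEFAULT_CELL_LINES[0], REFERENCE_DOSE_UM, REFERENCE_DURATION_H)]
    )

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta <= 1.0):
            raise ValueError(f"theta must be in [0, 1], got {self.theta}")
        if len(self.conditions) < 1:
            raise ValueError(f"compound {self.compound} has no conditions")

    @property
    def n_profiles(self) -> int:
        return len(self.conditions)


# ---------------------------------------------------------------------------
# compendium + disease cohort


@dataclass
class CompendiumTruth:
    """Ground truth returned with a synthetic compendium."""

    tissue_means: pd.DataFrame  # genes x tissues, relative expression
    gene_lengths: pd.Series  # kb
    batch_loadings: pd.Series  # 1.0 on batch-loaded genes, else 0.0
    batch_covariate: pd.Series  # +/- 0.5 per sample (empty if no batch)
    dispersion: float


@dataclass
class Compendium:
    counts: ExpressionMatrix
    tpm: ExpressionMatrix
    truth: CompendiumTruth
    spec: CompendiumSpec

    @property
    def meta(self) -> pd.DataFrame:
        return self.counts.meta

    @property
    def landmark_genes(self) -> pd.Index:
        return self.counts.genes[: self.spec.n_landmark]


def tpm_from_counts(counts: pd.DataFrame, gene_lengths_kb: pd.Series | None = None) -> pd.DataFrame:
    """Length-normalized counts rescaled so every column sums to 1e6."""
    if gene_lengths_kb is None:
        rate = counts.astype(float)
    else:
        rate = counts.astype(float).div(gene_lengths_kb, axis=0)
    total = rate.sum(axis=0)
    total = total.replace(0.0, 1.0)  # empty sample -> all-zero TPM column
    return rate.div(total, axis=1) * 1e6


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB draw with variance mu + phi mu^2 via the gamma-Poisson mixture."""
    mean = np.clip(mean, 1e-12, None)
    if phi <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / phi, scale=mean * phi)
    return rng.poisson(lam)


def generate_compendium(spec: CompendiumSpec) -> Compendium:
    """Simulate the healthy-tissue expression compendium.

    Each tissue has its own mean expression profile (a shared baseline
    modulated by tissue-specific log2 effects), counts are NB with
    dispersion ``spec.nb_dispersion``, and an optional batch factor
    multiplies a random gene subset by 2^(batch_strength * x) with
    x = +/-0.5 per sample.  TPM is derived from the counts with fixed
    1 kb gene lengths.
    """
    rng = _rng(spec.seed)
    genes = _gene_index(spec.n_genes)
    tissue_names = [t for t, _ in spec.tissues]

    # shared baseline (lognormal) modulated per tissue
    baseline = rng.lognormal(mean=2.0, sigma=1.5, size=spec.n_genes)
    effects = rng.normal(0.0, spec.tissue_effect_sd, size=(spec.n_genes, len(tissue_names)))
    tissue_means = pd.DataFrame(
        baseline[:, None] * 2.0 ** effects, index=genes, columns=tissue_names
    )

    n_batch_genes = int(round(spec.batch_gene_fraction * spec.n_genes))
    loaded = rng.choice(spec.n_genes, size=n_batch_genes, replace=False)
    loadings = pd.Series(0.0, index=genes)
    if spec.batch_strength > 0:
        loadings.iloc[loaded] = 1.0

    columns, tissues_col, batch_vals = [], [], []
    count_blocks = []
    for tissue, n in spec.tissues:
        mu_t = tissue_means[tissue].to_numpy()
        rel = mu_t / mu_t.sum()
        libsizes = rng.uniform(*spec.library_size_range, size=n)
        x = rng.choice([-0.5, 0.5], size=n)
        mu = rel[:, None] * libsizes[None, :]
        if spec.batch_strength > 0:
            mu = mu * 2.0 ** (spec.batch_strength * loadings.to_numpy()[:, None] * x[None, :])
        count_blocks.append(_nb_sample(rng, mu, spec.nb_dispersion))
        columns += [f"{tissue}_{i:04d}" for i in range(n)]
        tissues_col += [tissue] * n
        batch_vals += list(x)

    counts = pd.DataFrame(np.hstack(count_blocks), index=genes, columns=columns)
    meta = pd.DataFrame(
        {"tissue": tissues_col, "disease": "normal", "cohort": "compendium"},
        index=pd.Index(columns, name="sample_id"),
    )
    if spec.batch_strength > 0:
        meta["batch"] = batch_vals
        batch_cov = pd.Series(batch_vals, index=meta.index)
    else:
        batch_cov = pd.Series(dtype=float)

    gene_lengths = pd.Series(1.0, index=genes)
    tpm = tpm_from_counts(counts, gene_lengths)
    truth = CompendiumTruth(
        tissue_means=tissue_means,
        gene_lengths=gene_lengths,
        batch_loadings=loadings,
        batch_covariate=batch_cov,
        dispersion=spec.nb_dispersion,
    )
    return Compendium(
        counts=ExpressionMatrix(counts, meta, "counts"),
        tpm=ExpressionMatrix(tpm, meta.copy(), "tpm"),
        truth=truth,
        spec=spec,
    )


def generate_disease_cohort(
    compendium: Compendium,
    planted: PlantedSignature,
    n: int | None = None,
    *,
    disease_label: str = "disease",
    seed: int = 1,
) -> ExpressionMatrix:
    """Draw disease samples from the source-tissue model with planted effects.

    Means on the planted genes are multiplied by 2^effect_log2fc;
    control genes (and every other gene) keep the source-tissue mean.
    Returns a counts ExpressionMatrix whose metadata carries
    ``disease_label``; samples inherit the compendium's batch covariate
    scheme when one is present.
    """
    spec = compendium.spec
    if n is None:
        n = spec.n_disease_samples
    if n < 0:
        raise ValueError(f"negative cohort size: {n}")
    genes = compendium.counts.genes
    unknown = [g for g in planted.genes + list(planted.control_genes) if g not in genes]
    if unknown:
        raise KeyError(f"planted gene id not in compendium: {unknown[0]!r}")

    rng = _rng(seed)
    mu_t = compendium.truth.tissue_means[spec.source_tissue].copy()
    shift = planted.effect_log2fc.reindex(genes).fillna(0.0)
    mu_d = mu_t * 2.0 ** shift
    rel = (mu_d / mu_d.sum()).to_numpy()

    columns = [f"{disease_label}_{i:04d}" for i in range(n)]
    meta = pd.DataFrame(
        {"tissue": spec.source_tissue, "disease": disease_label, "cohort": disease_label},
        index=pd.Index(columns, name="sample_id"),
    )
    if n == 0:
        empty = pd.DataFrame(
            np.zeros((len(genes), 0), dtype=int), index=genes, columns=columns
        )
        return ExpressionMatrix(empty, meta, "counts")

    libsizes = rng.uniform(*spec.library_size_range, size=n)
    mu = rel[:, None] * libsizes[None, :]
    if spec.batch_strength > 0:
        x = rng.choice([-0.5, 0.5], size=n)
        loadings = compendium.truth.batch_loadings.to_numpy()
        mu = mu * 2.0 ** (spec.batch_strength * loadings[:, None] * x[None, :])
        meta["batch"] = x
    counts = pd.DataFrame(
        _nb_sample(rng, mu, spec.nb_dispersion), index=genes, columns=columns
    )
    return ExpressionMatrix(counts, meta, "counts")


# ---------------------------------------------------------------------------
# drug profiles, sensitivity


def _dose_time_factor(dose_um: float, duration_h: float) -> float:
    """Multiplicative strength modulation, clamped to [0.25, 1.5].

    Linear in log10(dose / 10 uM) and in duration relative to 24 h, so
    sub-reference conditions attenuate and supra-reference conditions
    amplify the planted reversal — giving the sRGES reference-condition
    correction something real to remove.
    """
    f = 1.0 + 0.3 * np.log10(dose_um / REFERENCE_DOSE_UM)
    f += 0.2 * (duration_h / REFERENCE_DURATION_H - 1.0)
    return float(np.clip(f, 0.25, 1.5))


def generate_drug_library(
    planted: PlantedSignature,
    compounds: list[PlantedCompound],
    *,
    landmark_genes: pd.Index,
    noise_sd: float = 0.3,
    seed: int = 2,
) -> ProfileLibrary:
    """Build a perturbation-profile library with planted reversal strengths.

    Each profile's differential vector is -theta_mod * effect_log2fc on
    the planted signature genes (so a reversing compound pushes
    disease-up genes down and vice versa) plus Gaussian noise with sd
    ``noise_sd`` on every landmark gene; theta_mod is theta scaled by
    the dose/duration factor.  Only signature genes inside the landmark
    universe receive signal.
    """
    if not compounds:
        raise ValueError("compound list is empty")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be nonnegative, got {noise_sd}")
    rng = _rng(seed)
    effect = planted.effect_log2fc.reindex(landmark_genes).fillna(0.0).to_numpy()

    rows, meta_rows, ids = [], [], []
    for comp in compounds:
        for j, (cell_line, dose, dur) in enumerate(comp.conditions):
            theta_mod = comp.theta * _dose_time_factor(dose, dur)
            vec = -theta_mod * effect + rng.normal(0.0, noise_sd, size=len(landmark_genes))
            pid = f"{comp.compound}_p{j:02d}"
            rows.append(vec)
            ids.append(pid)
            meta_rows.append((comp.compound, cell_line, dose, dur))
    values = pd.DataFrame(rows, index=pd.Index(ids, name="profile_id"), columns=landmark_genes)
    meta = pd.DataFrame(
        meta_rows,
        index=values.index,
        columns=["compound", "cell_line", "dose_um", "duration_h"],
    )
    truth = pd.DataFrame(
        {
            "compound": [c.compound for c in compounds],
            "theta": [c.theta for c in compounds],
            "moa_class": [c.moa_class for c in compounds],
            "clinical_phase": [c.clinical_phase for c in compounds],
            "n_profiles": [c.n_profiles for c in compounds],
        }
    ).set_index("compound")
    return ProfileLibrary(values=values, meta=meta, truth=truth)


def generate_sensitivity(
    compounds: list[PlantedCompound],
    cell_lines: tuple[str, ...] = DEFAULT_CELL_LINES,
    *,
    a: float = -4.0,
    b: float = 2.0,
    noise_sd: float = 0.25,
    low_quality_fraction: float = 0.1,
    seed: int = 3,
) -> tuple[SensitivityTable, pd.DataFrame]:
    """Simulate an AC50 screen monotone in reversal strength.

    AC50 (molar) = 10^(a - b*theta + eps) with eps ~ N(0, noise_sd), so
    stronger reversers are more potent in expectation.  A fraction of
    records is flagged low quality (cclass/cclass2 = 4) to exercise the
    curve-quality filter; the rest get flags in {1, 2, 3}.
    """
    if not compounds:
        raise ValueError("compound list is empty")
    if b < 0:
        raise ValueError(f"slope b must be nonnegative, got {b}")
    rng = _rng(seed)
    records = []
    for comp in compounds:
        for cl in cell_lines:
            eps = rng.normal(0.0, noise_sd)
            ac50 = 10.0 ** (a - b * comp.theta + eps)
            if rng.uniform() < low_quality_fraction:
                cclass, cclass2 = 4, 4
            else:
                cclass = int(rng.integers(1, 4))
                cclass2 = int(rng.integers(1, 4))
            records.append((comp.compound, cl, ac50, cclass, cclass2))
    table = pd.DataFrame(
        records, columns=["compound", "cell_line", "ac50", "cclass", "cclass2"]
    )
    truth = pd.DataFrame(
        {"compound": [c.compound for c in compounds], "theta": [c.theta for c in compounds]}
    ).set_index("compound")
    return SensitivityTable(table), truth


# ---------------------------------------------------------------------------
# single cell


def generate_sc_matrix(
    planted: PlantedSignature,
    genes: pd.Index,
    *,
    n_malignant: int = 2259,
    n_oligo: int = 232,
    programs: tuple[str, ...] = DEFAULT_PROGRAMS,
    program_module_size: int = 30,
    program_effect: float = 1.0,
    signature_effect_scale: float = 1.0,
    dropout: float = 0.3,
    base_log_sd: float = 1.0,
    seed: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]]]:
    """Simulate an RSEM-style single-cell matrix with labeled cells.

    Malignant cells carry the planted signature (log-mean shifted by
    effect_log2fc * ln 2 * signature_effect_scale) plus one of four
    disjoint program modules (cell cycle / OPC-like / AC-like /
    OC-like); oligodendrocytes are baseline.  Values are lognormal with
    zeros injected at rate ``dropout``.  Defaults mirror the emulated
    dataset's 2259 malignant and 232 oligodendrocyte cells.

    Returns (values genes x cells, labels per cell, program modules).
    """
    if n_malignant < 0 or n_oligo < 0:
        raise ValueError("cell counts must be nonnegative")
    if not (0.0 <= dropout < 1.0):
        raise ValueError(f"dropout must be in [0, 1), got {dropout}")
    rng = _rng(seed)
    n_cells = n_malignant + n_oligo
    gene_mean = rng.normal(1.0, 1.0, size=len(genes))

    sig_shift = (
        planted.effect_log2fc.reindex(genes).fillna(0.0).to_numpy()
        * np.log(2.0)
        * signature_effect_scale
    )

    # disjoint program modules drawn from non-signature genes
    free = [g for g in genes if g not in set(planted.genes)]
    modules: dict[str, list[str]] = {}
    pool = list(rng.permutation(free))
    for prog in programs:
        modules[prog] = pool[:program_module_size]
        pool = pool[program_module_size:]
    gene_pos = {g: i for i, g in enumerate(genes)}

    log_mu = np.tile(gene_mean[:, None], (1, n_cells))
    log_mu[:, :n_malignant] += sig_shift[:, None]
    assignment = rng.integers(0, len(programs), size=n_malignant) if programs else np.array([])
    for p_idx, prog in enumerate(programs):
        cells = np.flatnonzero(assignment == p_idx)
        idx = [gene_pos[g] for g in modules[prog]]
        for c in cells:
            log_mu[idx, c] += program_effect

    values = np.exp(log_mu + rng.normal(0.0, base_log_sd, size=log_mu.shape))
    if dropout > 0:
        values[rng.uniform(size=values.shape) < dropout] = 0.0

    cell_ids = [f"mal_{i:05d}" for i in range(n_malignant)] + [
        f"oligo_{i:05d}" for i in range(n_oligo)
    ]
    labels = pd.DataFrame(
        {
            "cell_type": ["malignant"] * n_malignant + ["oligodendrocyte"] * n_oligo,
            "program": [programs[k] for k in assignment] + [""] * n_oligo
            if len(programs)
            else [""] * n_cells,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    frame = pd.DataFrame(values, index=genes, columns=cell_ids)
    return frame, labels, modules


# ---------------------------------------------------------------------------
# helpers for assembling the default study scenario


def random_planted_signature(
    landmark_genes: pd.Index,
    *,
    n_up: int = 100,
    n_down: int = 100,
    n_control: int = 300,
    effect_low: float = 1.0,
    effect_high: float = 2.5,
    seed: int = 5,
) -> PlantedSignature:
    """Draw disjoint up/down/control gene sets from the landmark universe."""
    rng = _rng(seed)
    need = n_up + n_down + n_control
    if need > len(landmark_genes):
        raise ValueError(
            f"signature needs {need} genes but universe has {len(landmark_genes)}"
        )
    chosen = rng.choice(len(landmark_genes), size=need, replace=False)
    up = [landmark_genes[i] for i in chosen[:n_up]]
    down = [landmark_genes[i] for i in chosen[n_up : n_up + n_down]]
    ctrl = [landmark_genes[i] for i in chosen[n_up + n_down :]]
    lfc = pd.Series(
        np.concatenate(
            [
                rng.uniform(effect_low, effect_high, size=n_up),
                -rng.uniform(effect_low, effect_high, size=n_down),
            ]
        ),
        index=up + down,
    )
    return PlantedSignature(up_genes=up, down_genes=down, effect_log2fc=lfc, control_genes=ctrl)


def default_compound_panel(
    *,
    n_compounds: int = 100,
    n_strong: int = 10,
    cell_lines: tuple[str, ...] = DEFAULT_CELL_LINES,
    seed: int = 6,
) -> list[PlantedCompound]:
    """The default screening panel: 100 compounds, 10 strong reversers.

    Strong compounds (theta >= 0.75) are launched drugs with benign MOA
    classes and at least one profile per cell line; the remaining
    compounds span theta in [0, 0.7] with a mix of MOA classes —
    including the non-specific chemotherapy classes that the hit filter
    excludes — clinical phases, and profile counts from 1 to 12.
    """
    rng = _rng(seed)
    excluded_moas = ["TOP inhibitor", "CDK inhibitor", "HDAC inhibitor", "DNA inhibitor"]
    benign_moas = ["IMPDH inhibitor", "sodium channel blocker", "null", "EGFR inhibitor"]
    doses = [1.0, 5.0, 10.0, 20.0]
    durations = [6.0, 24.0, 48.0]
    compounds: list[PlantedCompound] = []
    thetas_strong = np.linspace(0.75, 1.0, n_strong)
    for i in range(n_compounds):
        name = f"C{i:03d}"
        if i < n_strong:
            theta = float(thetas_strong[i])
            moa = benign_moas[i % len(benign_moas)]
            phase = "Launched"
            conditions = [(cl, REFERENCE_DOSE_UM, REFERENCE_DURATION_H) for cl in cell_lines]
            extra = int(rng.integers(0, 9))
            for _ in range(extra):
                conditions.append(
                    (
                        cell_lines[int(rng.integers(0, len(cell_lines)))],
                        float(rng.choice(doses)),
                        float(rng.choice(durations)),
                    )
                )
        else:
            theta = float(rng.uniform(0.0, 0.7))
            r = rng.uniform()
            if r < 0.2:
                moa = excluded_moas[int(rng.integers(0, len(excluded_moas)))]
            else:
                moa = benign_moas[int(rng.integers(0, len(benign_moas)))]
            phase = "Preclinical" if rng.uniform() < 0.15 else "Launched"
            n_prof = int(rng.integers(1, 13))
            conditions = [
                (
                    cell_lines[int(rng.integers(0, len(cell_lines)))],
                    float(rng.choice(doses)),
                    float(rng.choice(durations)),
                )
                for _ in range(n_prof)
            ]
        compounds.append(
            PlantedCompound(
                compound=name,
                theta=theta,
                moa_class=moa,
                clinical_phase=phase,
                conditions=conditions,
            )
        )
    return compounds


def annotations_from_panel(compounds: list[PlantedCompound]) -> pd.DataFrame:
    """Drug-annotation table (MOA class, targets, clinical phase)."""
    return pd.DataFrame(
        {
            "compound": [c.compound for c in compounds],
            "moa_class": [c.moa_class for c in compounds],
            "targets": [c.moa_class.split(" ")[0] for c in compounds],
            "clinical_phase": [c.clinical_phase for c in compounds],
        }
    ).set_index("compound")
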