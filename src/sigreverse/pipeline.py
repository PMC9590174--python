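"""End-to-end orchestration of the signature-reversal analysis.

``run_pipeline`` executes the stages in order — simulate (optional) ->
select controls -> build signature -> score profiles -> evaluate ->
filter hits — writing every intermediate table, a provenance manifest
(package version, config hash, seed, per-stage row counts), and
returning the in-memory results.  One global seed fans out to
independent per-stage seeds through a counter-based scheme, so a stage
re-run in isolation reproduces its output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import DiseaseSignature, ExpressionMatrix, ProfileLibrary, SensitivityTable
from .disease_signature import (
    compute_de,
    remove_unwanted_variation,
    select_empirical_controls,
    threshold_signature,
)
from .io import (
    write_expression,
    write_profile_library,
    write_signature,
    write_table,
)
from .prediction_evaluation import (
    DEFAULT_EXCLUDED_MOAS,
    correlate_efficacy,
    filter_hits,
    filter_sensitivity,
    target_class_enrichment,
)
from .reference_selection import AutoencoderConfig, encode, select_controls, train_autoencoder
from .reversal_scoring import compute_rges_table, summarize_srges
from .synthetic_data import (
    Compendium,
    CompendiumSpec,
    annotations_from_panel,
    default_compound_panel,
    generate_compendium,
    generate_disease_cohort,
    generate_drug_library,
    generate_sensitivity,
    random_planted_signature,
    tpm_from_counts,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs", "stage_seed"]


def stage_seed(global_seed: int, stage_index: int) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    ss = np.random.SeedSequence([int(global_seed), int(stage_index)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """All stage parameters of the demo/synthetic pipeline.

    Defaults are the scaled-down study conditions the test suite runs
    under; the scoring-side defaults (top 100 signature genes, sRGES
    cutoff -0.1, curve-quality < 4, >= 3 profiles, the four excluded
    MOA classes) are the analysis conventions of the emulated study.
    """

    seed: int = 42
    # simulation scale
    n_genes: int = 1200
    n_landmark: int = 978
    tissues: list = field(default_factory=lambda: [("brain", 150), ("liver", 100)])
    source_tissue: str = "brain"
    n_disease_samples: int = 22
    batch_strength: float = 1.0
    n_sig_up: int = 100
    n_sig_down: int = 100
    n_sig_control: int = 300
    n_compounds: int = 100
    library_noise_sd: float = 0.3
    # autoencoder
    n_encoded: int = 64
    ae_epochs: int = 40
    ae_batch_size: int = 128
    ae_learning_rate: float = 2e-4
    ae_hidden_widths: list = field(default_factory=lambda: [512, 128])
    ae_dropout: float = 0.1
    # signature
    k_controls: int = 100
    ruv_k: int = 1
    empirical_n: int = 500
    lfc_min: float = 1.0
    padj_max: float = 0.05
    # scoring + evaluation
    top_n: int = 100
    srges_cutoff: float = -0.1
    max_cclass: int = 4
    min_profiles: int = 3
    exclude_moa: list = field(default_factory=lambda: sorted(DEFAULT_EXCLUDED_MOAS))
    exclude_preclinical: bool = True
    n_perm: int = 500

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        if isinstance(cfg.tissues, list):
            cfg.tissues = [tuple(t) for t in cfg.tissues]
        return cfg


@dataclass
class SyntheticBundle:
    """Everything the simulate stage produces."""

    compendium: Compendium
    cohort: ExpressionMatrix
    cohort_tpm: ExpressionMatrix
    planted: object
    library: ProfileLibrary
    sensitivity: SensitivityTable
    sensitivity_truth: pd.DataFrame
    annotations: pd.DataFrame


def simulate_bundle(config: PipelineConfig) -> SyntheticBundle:
    """Generate the full synthetic input bundle for one pipeline run."""
    spec = CompendiumSpec(
        n_genes=config.n_genes,
        n_landmark=config.n_landmark,
        tissues=[tuple(t) for t in config.tissues],
        n_disease_samples=config.n_disease_samples,
        source_tissue=config.source_tissue,
        batch_strength=config.batch_strength,
        seed=stage_seed(config.seed, 0),
    )
    compendium = generate_compendium(spec)
    landmarks = compendium.landmark_genes
    planted = random_planted_signature(
        landmarks,
        n_up=config.n_sig_up,
        n_down=config.n_sig_down,
        n_control=config.n_sig_control,
        seed=stage_seed(config.seed, 1),
    )
    cohort = generate_disease_cohort(compendium, planted, seed=stage_seed(config.seed, 2))
    cohort_tpm = ExpressionMatrix(
        tpm_from_counts(cohort.values, compendium.truth.gene_lengths),
        cohort.meta.copy(),
        "tpm",
    )
    panel = default_compound_panel(
        n_compounds=config.n_compounds, seed=stage_seed(config.seed, 3)
    )
    library = generate_drug_library(
        planted,
        panel,
        landmark_genes=landmarks,
        noise_sd=config.library_noise_sd,
        seed=stage_seed(config.seed, 4),
    )
    sensitivity, sens_truth = generate_sensitivity(panel, seed=stage_seed(config.seed, 5))
    annotations = annotations_from_panel(panel)
    return SyntheticBundle(
        compendium=compendium,
        cohort=cohort,
        cohort_tpm=cohort_tpm,
        planted=planted,
        library=library,
        sensitivity=sensitivity,
        sensitivity_truth=sens_truth,
        annotations=annotations,
    )


def validate_inputs(
    signature_genes,
    landmark_genes,
    srges_compounds,
    sensitivity: SensitivityTable,
    annotations: pd.DataFrame | None = None,
) -> dict:
    """Pre-compute sanity report: overlaps, duplicates, unit checks."""
    report: dict = {"checks": [], "warnings": []}
    sig = set(signature_genes)
    landmarks = set(landmark_genes)
    overlap = len(sig & landmarks) / max(len(sig), 1)
    report["signature_landmark_overlap_pct"] = round(100 * overlap, 1)
    if overlap == 0:
        report["warnings"].append("signature and landmark gene universes are disjoint")
    sens_compounds = set(sensitivity.records["compound"])
    pred = set(srges_compounds)
    comp_overlap = len(pred & sens_compounds) / max(len(pred), 1)
    report["prediction_sensitivity_overlap_pct"] = round(100 * comp_overlap, 1)
    if comp_overlap == 0:
        report["warnings"].append("no compounds shared between predictions and sensitivity")
    if len(sensitivity) and (sensitivity.records["ac50"] <= 0).any():
        report["warnings"].append("non-positive AC50 values present")
    else:
        report["checks"].append("AC50 values positive")
    if annotations is not None:
        dupes = annotations.index[annotations.index.duplicated()].tolist()
        if dupes:
            report["warnings"].append(f"duplicated compound ids in annotations: {dupes[:5]}")
        else:
            report["checks"].append("annotation compound ids unique")
    return report


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage on a synthetic bundle and write the run directory.

    Outputs: controls.tsv, signature.tsv, rges.tsv, srges.tsv,
    evaluation.json, enrichment.tsv, hits.tsv, validation.json and
    manifest.json.  Each TSV carries a header comment with the config
    hash and seed.  Raises with the failing stage's name; outputs of
    completed stages are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = [f"config_hash={config.config_hash()}", f"seed={config.seed}"]
    manifest: dict = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    results: dict = {}
    stage = "simulate"
    t0 = time.time()
    try:
        bundle = simulate_bundle(config)
        results["bundle"] = bundle
        write_expression(
            bundle.cohort, outdir / "cohort_counts.tsv.gz", outdir / "cohort_meta.tsv",
            header_lines=header,
        )
        write_profile_library(bundle.library, outdir / "profiles.tsv.gz", header_lines=header)
        write_table(bundle.sensitivity.records, outdir / "sensitivity.tsv", header_lines=header)
        write_table(
            bundle.annotations.reset_index(), outdir / "annotations.tsv", header_lines=header
        )
        manifest["stages"][stage] = {
            "n_normals": int(bundle.compendium.counts.values.shape[1]),
            "n_disease": int(bundle.cohort.values.shape[1]),
            "n_profiles": int(len(bundle.library.profile_ids)),
            "seconds": round(time.time() - t0, 2),
        }

        stage = "select_controls"
        t0 = time.time()
        ae_config = AutoencoderConfig(
            n_encoded=config.n_encoded,
            batch_size=config.ae_batch_size,
            epochs=config.ae_epochs,
            learning_rate=config.ae_learning_rate,
            hidden_widths=list(config.ae_hidden_widths),
            dropout_rate=config.ae_dropout,
            seed=stage_seed(config.seed, 10),
        )
        full_tpm = pd.concat(
            [bundle.compendium.tpm.values, bundle.cohort_tpm.values], axis=1
        )
        model = train_autoencoder(full_tpm, ae_config)
        normal_emb = encode(model, bundle.compendium.tpm.values)
        disease_emb = encode(model, bundle.cohort_tpm.values)
        controls = select_controls(disease_emb, normal_emb, k=config.k_controls)
        results["controls"] = controls
        results["encoder_model"] = model
        write_table(controls, outdir / "controls.tsv", header_lines=header)
        source_frac = (
            bundle.compendium.meta.loc[controls["sample_id"], "tissue"]
            == config.source_tissue
        ).mean()
        manifest["stages"][stage] = {
            "k": int(len(controls)),
            "source_tissue_fraction": round(float(source_frac), 3),
            "final_mse": round(model.final_mse, 5),
            "seconds": round(time.time() - t0, 2),
        }

        stage = "signature"
        t0 = time.time()
        control_counts = bundle.compendium.counts.values.loc[:, controls["sample_id"]]
        case_counts = bundle.cohort.values
        emp_n = min(config.empirical_n, config.n_genes)
        empirical = select_empirical_controls(case_counts, control_counts, n=emp_n)
        combined = pd.concat([case_counts, control_counts], axis=1)
        W = None
        if config.ruv_k > 0:
            _, W = remove_unwanted_variation(combined, empirical, k_factors=config.ruv_k)
        de = compute_de(case_counts, control_counts, covariates=W)
        signature = threshold_signature(
            de, lfc_min=config.lfc_min, padj_max=config.padj_max, provenance="bulk"
        )
        results["de"] = de
        results["signature"] = signature
        write_table(
            de.reset_index().rename(columns={"index": "gene"}),
            outdir / "de.tsv.gz",
            header_lines=header,
        )
        write_signature(signature, outdir / "signature.tsv", header_lines=header)
        manifest["stages"][stage] = {
            "n_tested": int(len(de)),
            "n_up": len(signature.up),
            "n_down": len(signature.down),
            "seconds": round(time.time() - t0, 2),
        }
        if len(signature) == 0:
            raise RuntimeError("signature stage produced an empty signature")

        stage = "score"
        t0 = time.time()
        rges = compute_rges_table(bundle.library, signature, top_n=config.top_n)
        srges = summarize_srges(rges)
        results["rges"] = rges
        results["srges"] = srges
        write_table(rges, outdir / "rges.tsv.gz", header_lines=header)
        write_table(srges, outdir / "srges.tsv", header_lines=header)
        manifest["stages"][stage] = {
            "n_profiles": int(len(rges)),
            "n_compounds": int(len(srges)),
            "seconds": round(time.time() - t0, 2),
        }

        stage = "evaluate"
        t0 = time.time()
        validation = validate_inputs(
            signature.genes,
            bundle.library.landmark_genes,
            srges["compound"],
            bundle.sensitivity,
            bundle.annotations,
        )
        (outdir / "validation.json").write_text(json.dumps(validation, indent=1))
        filtered = filter_sensitivity(bundle.sensitivity, max_cclass=config.max_cclass)
        r, p, n = correlate_efficacy(srges, filtered, srges_cutoff=config.srges_cutoff)
        enrichment = target_class_enrichment(
            srges,
            bundle.annotations,
            n_perm=config.n_perm,
            seed=stage_seed(config.seed, 20),
        )
        results["evaluation"] = {"pearson_r": r, "p": p, "n": n}
        results["enrichment"] = enrichment
        (outdir / "evaluation.json").write_text(
            json.dumps({"pearson_r": r, "p": p, "n": n}, indent=1)
        )
        write_table(enrichment, outdir / "enrichment.tsv", header_lines=header)
        manifest["stages"][stage] = {
            "pearson_r": round(r, 4),
            "p": float(f"{p:.3g}"),
            "n": n,
            "seconds": round(time.time() - t0, 2),
        }

        stage = "hits"
        t0 = time.time()
        hits = filter_hits(
            srges,
            bundle.annotations,
            srges_cutoff=config.srges_cutoff,
            exclude_moa=set(config.exclude_moa),
            min_profiles=config.min_profiles,
            exclude_preclinical=config.exclude_preclinical,
        )
        results["hits"] = hits
        write_table(hits, outdir / "hits.tsv", header_lines=header)
        manifest["stages"][stage] = {
            "n_hits": int(len(hits)),
            "seconds": round(time.time() - t0, 2),
        }
    except Exception as exc:
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("pipeline complete: %d hits", len(results["hits"]))
    return results
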