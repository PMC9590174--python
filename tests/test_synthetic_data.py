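"""Generators: determinism, planted structure, and marginal properties."""

import numpy as np
import pandas as pd
import pytest

from sigreverse.synthetic_data import (
    CompendiumSpec,
    PlantedCompound,
    PlantedSignature,
    default_compound_panel,
    generate_compendium,
    generate_disease_cohort,
    generate_drug_library,
    generate_sc_matrix,
    generate_sensitivity,
    random_planted_signature,
)


def _null_signature():
    return PlantedSignature(up_genes=[], down_genes=[], effect_log2fc=pd.Series(dtype=float))


class TestCompendium:
    def test_counts_are_nonnegative_integers_and_tpm_sums_to_1e6(self, small_compendium):
        counts = small_compendium.counts.values.to_numpy()
        assert (counts >= 0).all()
        assert np.allclose(counts, np.round(counts))
        colsums = small_compendium.tpm.values.sum(axis=0)
        assert np.allclose(colsums, 1e6, rtol=1e-6)

    def test_deterministic_under_seed(self):
        spec = CompendiumSpec(n_genes=200, n_landmark=100, tissues=[("brain", 5), ("liver", 5)], seed=7)
        a = generate_compendium(spec)
        b = generate_compendium(spec)
        assert a.counts.values.equals(b.counts.values)
        assert a.tpm.values.equals(b.tpm.values)

    def test_no_batch_column_when_strength_zero(self, small_compendium):
        assert small_compendium.spec.batch_strength == 0
        assert "batch" not in small_compendium.meta.columns
        assert len(small_compendium.truth.batch_covariate) == 0

    def test_batch_truth_round_trips(self):
        spec = CompendiumSpec(
            n_genes=200, n_landmark=100, tissues=[("brain", 8)], batch_strength=1.0, seed=9
        )
        comp = generate_compendium(spec)
        assert "batch" in comp.meta.columns
        assert comp.truth.batch_loadings.sum() == pytest.approx(0.1 * 200)

    def test_within_tissue_correlation_exceeds_between(self, small_compendium):
        logt = np.log2(small_compendium.tpm.values + 1.0)
        tissue = small_compendium.meta["tissue"]
        corr = np.corrcoef(logt.to_numpy().T)
        same = tissue.to_numpy()[:, None] == tissue.to_numpy()[None, :]
        off_diag = ~np.eye(len(tissue), dtype=bool)
        within = corr[same & off_diag].mean()
        between = corr[~same].mean()
        assert within > between

    @pytest.mark.parametrize(
        "field,value,match",
        [
            ("n_genes", 0, "n_genes"),
            ("n_landmark", 999, "n_landmark"),
            ("source_tissue", "kidney", "source_tissue"),
            ("nb_dispersion", -1.0, "nb_dispersion"),
            ("batch_strength", -0.5, "batch_strength"),
        ],
    )
    def test_invalid_spec_names_the_field(self, field, value, match):
        kwargs = dict(n_genes=100, n_landmark=50, tissues=[("brain", 4)], source_tissue="brain")
        kwargs[field] = value
        with pytest.raises(ValueError, match=match):
            CompendiumSpec(**kwargs)

    def test_tissue_needs_two_samples(self):
        with pytest.raises(ValueError, match="tissue"):
            CompendiumSpec(n_genes=100, n_landmark=50, tissues=[("brain", 1)], source_tissue="brain")


class TestDiseaseCohort:
    def test_planted_effect_shifts_mean_ratio(self, small_compendium):
        genes = small_compendium.counts.genes
        up = [genes[0]]
        sig = PlantedSignature(
            up_genes=up, down_genes=[], effect_log2fc=pd.Series({genes[0]: 2.0})
        )
        cohort = generate_disease_cohort(small_compendium, sig, 200, seed=41)
        nullc = generate_disease_cohort(small_compendium, _null_signature(), 200, seed=42)
        cpm_case = (cohort.values / cohort.values.sum(axis=0)).loc[genes[0]].mean()
        cpm_ctrl = (nullc.values / nullc.values.sum(axis=0)).loc[genes[0]].mean()
        # effect_log2fc = 2 -> ~4x mean ratio (tolerance 25%)
        assert cpm_case / cpm_ctrl == pytest.approx(4.0, rel=0.25)

    def test_null_effect_matches_source_tissue(self, small_compendium):
        cohort = generate_disease_cohort(small_compendium, _null_signature(), 150, seed=43)
        brain = small_compendium.counts.values.loc[
            :, (small_compendium.meta["tissue"] == "brain").to_numpy()
        ]
        cpm_cohort = np.log2((cohort.values / cohort.values.sum(axis=0)).mean(axis=1) * 1e6 + 1)
        cpm_brain = np.log2((brain / brain.sum(axis=0)).mean(axis=1) * 1e6 + 1)
        assert np.abs(cpm_cohort - cpm_brain).mean() < 0.2

    def test_zero_samples_yields_empty_matrix_with_gene_index(self, small_compendium):
        cohort = generate_disease_cohort(small_compendium, _null_signature(), 0)
        assert cohort.values.shape == (600, 0)
        assert cohort.values.index.equals(small_compendium.counts.genes)

    def test_unknown_gene_id_is_named(self, small_compendium):
        sig = PlantedSignature(
            up_genes=["NOT_A_GENE"], down_genes=[],
            effect_log2fc=pd.Series({"NOT_A_GENE": 1.0}),
        )
        with pytest.raises(KeyError, match="NOT_A_GENE"):
            generate_disease_cohort(small_compendium, sig, 5)


class TestDrugLibrary:
    def test_zero_theta_profile_is_pure_noise(self, planted, small_compendium):
        comp = [PlantedCompound(compound="null_drug", theta=0.0)]
        lib = generate_drug_library(
            planted, comp, landmark_genes=small_compendium.landmark_genes, noise_sd=0.3, seed=51
        )
        vals = lib.values.iloc[0]
        on_sig = vals[planted.up_genes].mean()
        assert abs(on_sig) < 0.2  # no systematic signal on signature genes

    def test_full_reversal_noiseless_ranks_up_genes_at_bottom(self, planted, small_compendium):
        comp = [PlantedCompound(compound="perfect", theta=1.0)]
        lib = generate_drug_library(
            planted, comp, landmark_genes=small_compendium.landmark_genes, noise_sd=0.0, seed=52
        )
        ranking = lib.ranking(lib.profile_ids[0])
        pos = {g: i for i, g in enumerate(ranking)}
        non_sig = [g for g in small_compendium.landmark_genes if g not in set(planted.genes)]
        worst_non_sig = max(pos[g] for g in non_sig)
        assert all(pos[g] > worst_non_sig for g in planted.up_genes)

    def test_theta_scales_signal_linearly(self, planted, small_compendium):
        lib_half = generate_drug_library(
            planted, [PlantedCompound(compound="c", theta=0.5)],
            landmark_genes=small_compendium.landmark_genes, noise_sd=0.0, seed=53,
        )
        lib_full = generate_drug_library(
            planted, [PlantedCompound(compound="c", theta=1.0)],
            landmark_genes=small_compendium.landmark_genes, noise_sd=0.0, seed=53,
        )
        m_half = lib_half.values.iloc[0][planted.up_genes].mean()
        m_full = lib_full.values.iloc[0][planted.up_genes].mean()
        assert m_full == pytest.approx(2.0 * m_half)
        assert m_full < 0

    def test_negative_noise_sd_rejected(self, planted, small_compendium):
        with pytest.raises(ValueError, match="noise_sd"):
            generate_drug_library(
                planted, [PlantedCompound(compound="c", theta=0.5)],
                landmark_genes=small_compendium.landmark_genes, noise_sd=-0.1,
            )

    def test_truth_table_round_trips(self, library, compound_panel):
        assert len(library.truth) == len(compound_panel)
        assert (library.truth["n_profiles"] >= 1).all()


class TestSensitivity:
    def test_noiseless_ac50_strictly_decreasing_in_theta(self):
        comps = [PlantedCompound(compound=f"c{i}", theta=t) for i, t in enumerate([0.1, 0.5, 0.9])]
        table, _ = generate_sensitivity(comps, cell_lines=("cl1",), noise_sd=0.0,
                                        low_quality_fraction=0.0, seed=61)
        ac50 = table.records.set_index("compound")["ac50"]
        assert ac50["c0"] > ac50["c1"] > ac50["c2"]

    def test_closed_form_at_theta_one(self):
        comps = [PlantedCompound(compound="c", theta=1.0)]
        table, _ = generate_sensitivity(comps, cell_lines=("cl1",), a=-4.0, b=2.0,
                                        noise_sd=0.0, low_quality_fraction=0.0)
        assert table.records["ac50"].iloc[0] == pytest.approx(1e-6)

    def test_quality_fraction_zero_all_records_strong(self):
        comps = [PlantedCompound(compound=f"c{i}", theta=0.5) for i in range(20)]
        table, _ = generate_sensitivity(comps, noise_sd=0.1, low_quality_fraction=0.0, seed=62)
        assert ((table.records["cclass"] < 4) & (table.records["cclass2"] < 4)).all()

    def test_empty_compound_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            generate_sensitivity([])


class TestSingleCell:
    def test_default_shape_matches_emulated_dataset(self, planted, small_compendium):
        genes = small_compendium.landmark_genes[:50]
        values, labels, _ = generate_sc_matrix(planted, genes, seed=71)
        # 2259 malignant + 232 oligodendrocyte cells
        assert values.shape == (50, 2491)
        assert (labels["cell_type"] == "malignant").sum() == 2259
        assert (labels["cell_type"] == "oligodendrocyte").sum() == 232

    def test_null_effect_gives_no_group_difference(self, planted, small_compendium):
        genes = small_compendium.landmark_genes[:100]
        values, labels, _ = generate_sc_matrix(
            planted, genes, n_malignant=300, n_oligo=300, programs=(),
            signature_effect_scale=0.0, dropout=0.0, seed=72,
        )
        logx = np.log(values + 0.1)
        mal = logx.loc[:, (labels["cell_type"] == "malignant").to_numpy()].mean(axis=1)
        oligo = logx.loc[:, (labels["cell_type"] == "oligodendrocyte").to_numpy()].mean(axis=1)
        assert np.abs(mal - oligo).max() < 0.35

    def test_dropout_injects_zeros(self, planted, small_compendium):
        genes = small_compendium.landmark_genes[:50]
        values, _, _ = generate_sc_matrix(
            planted, genes, n_malignant=100, n_oligo=50, dropout=0.4, seed=73
        )
        zero_rate = (values.to_numpy() == 0).mean()
        assert zero_rate == pytest.approx(0.4, abs=0.05)

    def test_program_modules_are_disjoint(self, planted, small_compendium):
        genes = small_compendium.landmark_genes[:300]
        _, _, modules = generate_sc_matrix(
            planted, genes, n_malignant=40, n_oligo=10, seed=74
        )
        all_genes = [g for mod in modules.values() for g in mod]
        assert len(all_genes) == len(set(all_genes))
        assert not set(all_genes) & set(planted.genes)

    def test_negative_cell_counts_rejected(self, planted, small_compendium):
        with pytest.raises(ValueError, match="nonnegative"):
            generate_sc_matrix(planted, small_compendium.landmark_genes[:10], n_malignant=-1)


class TestPanelHelpers:
    def test_planted_signature_sets_are_disjoint(self, planted):
        assert not set(planted.up_genes) & set(planted.down_genes)
        assert not set(planted.control_genes) & set(planted.genes)

    def test_default_panel_strong_compounds_survive_confidence_filters(self):
        panel = default_compound_panel(seed=81)
        strong = [c for c in panel if c.theta >= 0.75]
        assert len(strong) == 10
        for c in strong:
            assert c.n_profiles >= 3
            assert c.clinical_phase != "Preclinical"
            assert "inhibitor" not in c.moa_class.lower() or c.moa_class in (
                "IMPDH inhibitor", "EGFR inhibitor"
            )

    def test_theta_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="theta"):
            PlantedCompound(compound="bad", theta=1.5)
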