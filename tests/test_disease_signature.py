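"""Signature construction: RUV, NB differential expression, sc t-tests."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from sigreverse.datatypes import DiseaseSignature
from sigreverse.disease_signature import (
    bh_adjust,
    combine_signatures,
    compute_de,
    evaluate_signature,
    remove_unwanted_variation,
    sc_de_table,
    sc_signature,
    select_empirical_controls,
    threshold_signature,
)
from sigreverse.synthetic_data import (
    CompendiumSpec,
    PlantedSignature,
    generate_compendium,
    generate_disease_cohort,
)


def _null_signature():
    return PlantedSignature(up_genes=[], down_genes=[], effect_log2fc=pd.Series(dtype=float))


class TestBhAdjust:
    def test_hand_computed_example(self):
        # p = [0.01, 0.02, 0.03], m = 3: step-up gives 0.03 for all three
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=100)
        adj = bh_adjust(p)
        assert ((adj >= p - 1e-12) & (adj <= 1.0)).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestEmpiricalControls:
    def test_planted_genes_are_excluded(self, small_compendium, planted, cohort):
        brain = small_compendium.counts.values.loc[
            :, (small_compendium.meta["tissue"] == "brain").to_numpy()
        ]
        controls = select_empirical_controls(cohort.values, brain, n=300)
        hit = len(set(controls) & set(planted.genes)) / len(planted.genes)
        assert hit <= 0.01  # >= 99% of planted genes kept out of the control set

    def test_n_equal_to_gene_count_returns_all(self, small_compendium, cohort):
        brain = small_compendium.counts.values.loc[
            :, (small_compendium.meta["tissue"] == "brain").to_numpy()
        ]
        controls = select_empirical_controls(cohort.values, brain, n=600)
        assert set(controls) == set(small_compendium.counts.genes)

    def test_n_too_large_rejected(self, small_compendium, cohort):
        brain = small_compendium.counts.values.loc[
            :, (small_compendium.meta["tissue"] == "brain").to_numpy()
        ]
        with pytest.raises(ValueError, match="600"):
            select_empirical_controls(cohort.values, brain, n=601)


class TestRuv:
    def test_k_zero_is_identity_on_centered_log(self, small_compendium):
        counts = small_compendium.counts.values.iloc[:, :20]
        adjusted, W = remove_unwanted_variation(counts, list(counts.index[:50]), 0)
        assert W.shape == (20, 0)
        lib = counts.sum(axis=0).replace(0, 1)
        logx = np.log2(counts.add(0.5).div(lib + 1.0, axis=1) * 1e6)
        expected = logx.sub(logx.mean(axis=1), axis=0)
        assert np.allclose(adjusted.to_numpy(), expected.to_numpy())

    def test_recovers_planted_batch_factor(self):
        spec = CompendiumSpec(
            n_genes=800, n_landmark=400, tissues=[("brain", 40)], batch_strength=1.5, seed=33
        )
        comp = generate_compendium(spec)
        controls = list(comp.counts.genes[:400])
        _, W = remove_unwanted_variation(comp.counts.values, controls, 1)
        r = np.corrcoef(W["W1"], comp.truth.batch_covariate)[0, 1]
        assert abs(r) > 0.9

    def test_constant_controls_leave_data_unchanged(self):
        rng = np.random.default_rng(5)
        profile = rng.poisson(50, size=30)  # every sample identical
        counts = pd.DataFrame(
            np.tile(profile[:, None], (1, 10)),
            index=[f"g{i}" for i in range(30)],
            columns=[f"s{i}" for i in range(10)],
        )
        adjusted, W = remove_unwanted_variation(counts, [f"g{i}" for i in range(5)], 1)
        assert np.allclose(W.to_numpy(), 0.0, atol=1e-8)
        centered, _ = remove_unwanted_variation(counts, [f"g{i}" for i in range(5)], 0)
        assert np.allclose(adjusted.to_numpy(), centered.to_numpy())

    def test_k_exceeding_samples_rejected(self, small_compendium):
        counts = small_compendium.counts.values.iloc[:, :5]
        with pytest.raises(ValueError, match="n_samples"):
            remove_unwanted_variation(counts, list(counts.index[:10]), 5)


class TestComputeDe:
    def test_identical_groups_give_zero_lfc(self, small_compendium):
        brain = small_compendium.counts.values.iloc[:, :6]
        dup = brain.copy()
        dup.columns = [f"{c}_dup" for c in brain.columns]
        de = compute_de(brain, dup)
        assert np.abs(de["log2fc"]).max() < 1e-6

    def test_too_few_samples_rejected(self, small_compendium):
        counts = small_compendium.counts.values
        with pytest.raises(ValueError, match="2 samples"):
            compute_de(counts.iloc[:, :1], counts.iloc[:, 1:5])

    def test_non_integer_input_suggests_tpm_mixup(self, small_compendium):
        tpm = small_compendium.tpm.values
        with pytest.raises(ValueError, match="TPM"):
            compute_de(tpm.iloc[:, :5], tpm.iloc[:, 5:10])

    def test_planted_signal_is_recovered(self, small_compendium, planted, cohort):
        brain = small_compendium.counts.values.loc[
            :, (small_compendium.meta["tissue"] == "brain").to_numpy()
        ].iloc[:, :10]
        de = compute_de(cohort.values, brain)
        sig = threshold_signature(de)
        found = len(set(sig.up) & set(planted.up_genes)) / len(planted.up_genes)
        assert found >= 0.7
        # adjusted p never below raw p
        assert (de["padj"] >= de["p"] - 1e-12).all()

    def test_matches_edger_on_shared_input(self, small_compendium, planted, cohort):
        """Cross-check against edgeR's exactTest as an independent oracle:
        effect estimates agree and discovery sets overlap strongly."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        brain = small_compendium.counts.values.loc[
            :, (small_compendium.meta["tissue"] == "brain").to_numpy()
        ].iloc[:, :10]
        case = cohort.values.iloc[:300]
        ctrl = brain.iloc[:300]
        de = compute_de(case, ctrl, min_cpm=1.0)

        import tempfile
        from pathlib import Path

        with tempfile.TemporaryDirectory() as td:
            td = Path(td)
            pd.concat([case, ctrl], axis=1).to_csv(td / "counts.tsv", sep="\t")
            script = textwrap.dedent(
                f"""
                suppressMessages(library(edgeR))
                counts <- read.delim("{td}/counts.tsv", row.names = 1, check.names = FALSE)
                group <- factor(c(rep("case", {case.shape[1]}), rep("ctrl", {ctrl.shape[1]})),
                                levels = c("ctrl", "case"))
                y <- DGEList(counts = counts, group = group)
                keep <- filterByExpr(y)
                y <- y[keep, , keep.lib.sizes = FALSE]
                y <- calcNormFactors(y)
                y <- estimateDisp(y)
                res <- topTags(exactTest(y), n = Inf)$table
                write.table(res, "{td}/edger.tsv", sep = "\t", quote = FALSE)
                """
            )
            (td / "run.R").write_text(script)
            subprocess.run(
                ["Rscript", str(td / "run.R")], check=True, capture_output=True, text=True
            )
            edger = pd.read_csv(td / "edger.tsv", sep="\t")
        shared = de.index.intersection(edger.index)
        assert len(shared) > 100
        r = np.corrcoef(de.loc[shared, "log2fc"], edger.loc[shared, "logFC"])[0, 1]
        assert r > 0.95
        ours = set(de.loc[shared].query("padj < 0.05 and abs(log2fc) > 1").index)
        theirs = set(edger.loc[shared].query("FDR < 0.05 and abs(logFC) > 1").index)
        if theirs:
            jaccard = len(ours & theirs) / len(ours | theirs)
            assert jaccard > 0.6


class TestThresholdSignature:
    @pytest.mark.parametrize(
        "lfc,padj,expected",
        [
            (1.2, 0.03, "up"),
            (1.2, 0.06, None),  # fails the adjusted-p threshold
            (-1.5, 0.001, "down"),
            (0.9, 0.001, None),  # fails the fold-change threshold
            (1.0, 0.03, None),  # strict inequality at the boundary
        ],
    )
    def test_threshold_boundaries(self, lfc, padj, expected):
        de = pd.DataFrame(
            {"log2fc": [lfc], "p": [padj / 2], "padj": [padj], "mean_expr": [5.0]},
            index=["gene1"],
        )
        sig = threshold_signature(de)
        if expected == "up":
            assert sig.up == ["gene1"]
        elif expected == "down":
            assert sig.down == ["gene1"]
        else:
            assert len(sig) == 0

    def test_ordering_by_abs_lfc_then_id(self):
        de = pd.DataFrame(
            {
                "log2fc": [1.5, 2.5, 1.5, -3.0],
                "p": [0.001] * 4,
                "padj": [0.01] * 4,
                "mean_expr": [5.0] * 4,
            },
            index=["b", "a", "aa", "c"],
        )
        sig = threshold_signature(de)
        assert sig.up == ["a", "aa", "b"]
        assert sig.down == ["c"]


class TestScSignature:
    def test_hand_computed_t_statistic(self):
        """log values [1,2,3] vs [4,5,6]: pooled-variance t = -3.674, df = 4."""
        vals = pd.DataFrame(
            [np.exp([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]) - 0.1],
            index=["g1"],
            columns=[f"c{i}" for i in range(6)],
        )
        labels = pd.Series(
            ["malignant"] * 3 + ["oligodendrocyte"] * 3, index=vals.columns
        )
        de = sc_de_table(vals, labels, var_min=0.0)
        assert de.loc["g1", "t"] == pytest.approx(-3.674, abs=1e-3)
        # two-sided p at df = 4 for |t| = 3.674
        assert de.loc["g1", "p"] == pytest.approx(0.0213, abs=2e-3)

    def test_low_variance_genes_removed(self, planted, small_compendium):
        from sigreverse.synthetic_data import generate_sc_matrix

        genes = small_compendium.landmark_genes[:80]
        values, labels, _ = generate_sc_matrix(
            planted, genes, n_malignant=60, n_oligo=40, dropout=0.0, seed=91
        )
        values.iloc[0] = 7.0  # constant gene: variance 0 < 0.1
        de = sc_de_table(values, labels)
        assert values.index[0] not in de.index

    def test_identical_groups_excluded_by_threshold(self):
        rng = np.random.default_rng(17)
        base = rng.lognormal(1.0, 1.0, size=(30, 4))
        vals = pd.DataFrame(
            np.hstack([base, base]),
            index=[f"g{i}" for i in range(30)],
            columns=[f"c{i}" for i in range(8)],
        )
        labels = pd.Series(["malignant"] * 4 + ["oligodendrocyte"] * 4, index=vals.columns)
        sig = sc_signature(vals, labels)
        assert len(sig) == 0

    def test_single_cell_group_rejected(self):
        vals = pd.DataFrame(
            [[1.0, 2.0, 3.0]], index=["g1"], columns=["c1", "c2", "c3"]
        )
        labels = pd.Series(["malignant", "oligodendrocyte", "oligodendrocyte"], index=vals.columns)
        with pytest.raises(ValueError, match="< 2"):
            sc_signature(vals, labels)

    def test_recovers_planted_signature(self, planted, small_compendium):
        from sigreverse.synthetic_data import generate_sc_matrix

        values, labels, _ = generate_sc_matrix(
            planted, small_compendium.landmark_genes, n_malignant=450, n_oligo=150,
            dropout=0.2, seed=92,
        )
        sig = sc_signature(values, labels)
        assert sig.provenance == "sc"
        recovered = len(set(sig.up) & set(planted.up_genes)) / len(planted.up_genes)
        assert recovered >= 0.7


class TestCombineSignatures:
    def _sig(self, up, down, lfc):
        return DiseaseSignature(up=up, down=down, lfc=pd.Series(lfc), provenance="bulk")

    def test_idempotent(self):
        a = self._sig(["g1"], ["g2"], {"g1": 2.0, "g2": -2.0})
        meta = combine_signatures(a, a)
        assert meta.up == ["g1"] and meta.down == ["g2"]
        assert meta.lfc["g1"] == pytest.approx(2.0)
        assert meta.provenance == "meta"

    def test_intersection_drops_one_sided_genes(self):
        a = self._sig(["g1", "g3"], [], {"g1": 2.0, "g3": 1.5})
        b = self._sig(["g1"], [], {"g1": 1.0})
        meta = combine_signatures(a, b, rule="intersection")
        assert meta.up == ["g1"]
        assert meta.lfc["g1"] == pytest.approx(1.5)  # mean of 2.0 and 1.0

    def test_union_keeps_one_sided_genes(self):
        a = self._sig(["g1", "g3"], [], {"g1": 2.0, "g3": 1.5})
        b = self._sig(["g1"], [], {"g1": 1.0})
        meta = combine_signatures(a, b, rule="union")
        assert set(meta.up) == {"g1", "g3"}

    def test_direction_conflicts_are_excluded(self):
        a = self._sig(["g1"], [], {"g1": 2.0})
        b = self._sig([], ["g1"], {"g1": -2.0})
        meta = combine_signatures(a, b, rule="union")
        assert len(meta) == 0


class TestEvaluateSignature:
    def test_truth_signature_predicts_sensitivity(
        self, truth_signature, library, sensitivity_bundle
    ):
        sens, _ = sensitivity_bundle
        r, p, n = evaluate_signature(truth_signature, library, sens)
        assert r > 0
        assert p < 0.01
        assert n >= 20

    def test_permuted_signature_loses_the_correlation(
        self, truth_signature, library, sensitivity_bundle, small_compendium
    ):
        sens, _ = sensitivity_bundle
        rng = np.random.default_rng(7)
        genes = list(small_compendium.landmark_genes)
        relabel = dict(zip(truth_signature.genes, rng.permutation(genes)[: len(truth_signature)]))
        permuted = DiseaseSignature(
            up=[relabel[g] for g in truth_signature.up],
            down=[relabel[g] for g in truth_signature.down],
            lfc=pd.Series(
                truth_signature.lfc.to_numpy(),
                index=[relabel[g] for g in truth_signature.genes],
            ),
        )
        try:
            r, _, _ = evaluate_signature(permuted, library, sens)
            assert abs(r) < 0.5
        except ValueError:
            pass  # too few compounds pass the cutoff under a random signature

    def test_empty_sensitivity_is_an_error(self, truth_signature, library):
        from sigreverse.datatypes import SensitivityTable

        empty = SensitivityTable(
            pd.DataFrame(columns=["compound", "cell_line", "ac50", "cclass", "cclass2"])
        )
        with pytest.raises(ValueError):
            evaluate_signature(truth_signature, library, empty)
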