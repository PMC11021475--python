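"""Immune-axis discovery: PCA, correlations, clustering, signature selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import umiskit as uk
from umiskit.discovery import (
    CorrelationMatrix,
    candidate_pcs,
    cluster_genesets,
    correlate_pcs_with_genesets,
    identify_immune_axis,
    run_pca,
    score_genesets_per_sample,
    select_signature,
)
from umiskit.expression import ExpressionMatrix
from umiskit.genesets import GeneSet, GeneSetCollection


def _log_matrix(values, genes, samples):
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), unit="log"
    )


class TestRunPca:
    def _planted_axis(self):
        rng = np.random.default_rng(0)
        axis = rng.normal(size=12)
        loadings = rng.normal(size=30)
        values = np.outer(loadings, axis) * 3 + rng.normal(0, 0.1, (30, 12))
        return _log_matrix(values, [f"g{i}" for i in range(30)], [f"s{i}" for i in range(12)])

    def test_planted_dominant_axis_tops_variance(self):
        pca = run_pca(self._planted_axis(), n_components=5)
        evf = pca.explained_variance_fraction
        assert evf[0] > max(evf[1:])
        assert np.all(np.diff(evf) <= 1e-12)

    def test_loadings_orthonormal(self):
        pca = run_pca(self._planted_axis(), n_components=5)
        gram = pca.loadings.to_numpy().T @ pca.loadings.to_numpy()
        assert np.allclose(gram, np.eye(5), atol=1e-8)

    def test_full_reconstruction(self):
        m = self._planted_axis()
        pca = run_pca(m, n_components=11)
        centered = m.values.to_numpy().T - m.values.to_numpy().T.mean(axis=0)
        recon = pca.scores.to_numpy() @ pca.loadings.to_numpy().T
        assert np.allclose(recon, centered, atol=1e-6)

    def test_sign_convention_deterministic(self):
        m = self._planted_axis()
        pca = run_pca(m, n_components=3)
        for col in pca.loadings.columns:
            pivot = pca.loadings[col].abs().idxmax()
            assert pca.loadings.loc[pivot, col] > 0

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError, match="n_components"):
            run_pca(self._planted_axis(), n_components=12)

    def test_recovers_latent_theta_on_synthetic_cohort(self, normalized_cohort):
        log_matrix, _, truth = normalized_cohort
        top = uk.select_top_variance_genes(log_matrix, 0.10)
        pca = run_pca(log_matrix.subset_genes(top), n_components=5)
        rhos = [
            abs(spearmanr(pca.scores[f"PC{i}"], truth.theta).statistic) for i in (1, 2, 3)
        ]
        assert max(rhos) >= 0.8


class TestGeneSetScores:
    def test_single_sample_property(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(40)]
        base = pd.DataFrame(rng.uniform(1, 100, (40, 4)), index=genes, columns=list("abcd"))
        sets = GeneSetCollection()
        sets.add(GeneSet("S1", up=genes[:5]))
        tpm4 = ExpressionMatrix(base, unit="tpm")
        extra = base.copy()
        extra["e"] = rng.uniform(1, 100, 40)
        tpm5 = ExpressionMatrix(extra, unit="tpm")
        s4 = score_genesets_per_sample(tpm4, sets)
        s5 = score_genesets_per_sample(tpm5, sets)
        pd.testing.assert_frame_equal(s4, s5.loc[list("abcd")])

    def test_empty_intersection_set_skipped_with_warning(self):
        genes = [f"g{i}" for i in range(10)]
        tpm = ExpressionMatrix(
            pd.DataFrame(np.arange(20.0).reshape(10, 2), index=genes, columns=["a", "b"]),
            unit="tpm",
        )
        sets = GeneSetCollection()
        sets.add(GeneSet("OK", up=genes[:3]))
        sets.add(GeneSet("MISSING", up=["zz1", "zz2"]))
        with pytest.warns(UserWarning, match="MISSING"):
            scores = score_genesets_per_sample(tpm, sets)
        assert list(scores.columns) == ["OK"]

    def test_planted_immune_set_tracks_theta(self, normalized_cohort, default_config):
        _, tpm, truth = normalized_cohort
        sets = GeneSetCollection()
        sets.add(GeneSet("PLANTED", up=truth.immune_gene_ids))
        scores = score_genesets_per_sample(tpm, sets)
        rho = spearmanr(scores["PLANTED"], truth.theta.reindex(scores.index)).statistic
        assert rho >= 0.8


class TestCorrelatePcs:
    def _pca_stub(self, coords: dict[str, list[float]], samples):
        scores = pd.DataFrame(coords, index=samples)
        loadings = pd.DataFrame(np.eye(len(coords)), columns=scores.columns)
        from umiskit.discovery import PcaResult

        return PcaResult(scores, loadings, np.linspace(0.5, 0.1, len(coords)))

    def test_monotone_pairs(self):
        samples = list("abcd")
        pca = self._pca_stub({"PC1": [1, 2, 3, 4]}, samples)
        up = pd.DataFrame({"S": [10, 20, 30, 40]}, index=samples)
        down = pd.DataFrame({"S": [40, 30, 20, 10]}, index=samples)
        assert correlate_pcs_with_genesets(pca, up, pcs=[1]).rho.loc["S", "PC1"] == 1.0
        assert correlate_pcs_with_genesets(pca, down, pcs=[1]).rho.loc["S", "PC1"] == -1.0

    def test_hand_spearman(self):
        samples = list("abcd")
        pca = self._pca_stub({"PC1": [1, 2, 3, 4]}, samples)
        scores = pd.DataFrame({"S": [10, 30, 20, 40]}, index=samples)
        rho = correlate_pcs_with_genesets(pca, scores, pcs=[1]).rho.loc["S", "PC1"]
        assert rho == pytest.approx(0.8)

    def test_constant_scores_recorded_missing(self):
        samples = list("abcd")
        pca = self._pca_stub({"PC1": [1, 2, 3, 4]}, samples)
        scores = pd.DataFrame({"S": [5, 5, 5, 5]}, index=samples)
        assert np.isnan(correlate_pcs_with_genesets(pca, scores, pcs=[1]).rho.loc["S", "PC1"])


class TestClusterGenesets:
    def test_separated_blocks_recovered(self):
        rho = pd.DataFrame(
            {
                "PC1": [0.9, 0.85, 0.88, -0.7, -0.75],
                "PC2": [0.1, 0.05, 0.12, 0.8, 0.82],
            },
            index=["a1", "a2", "a3", "b1", "b2"],
        )
        labels = cluster_genesets(CorrelationMatrix(rho), k=2)
        assert len(set(labels[["a1", "a2", "a3"]])) == 1
        assert len(set(labels[["b1", "b2"]])) == 1
        assert labels["a1"] != labels["b1"]

    def test_k_equals_n_gives_singletons(self):
        rho = pd.DataFrame(np.eye(4), index=list("abcd"), columns=[f"PC{i}" for i in range(1, 5)])
        labels = cluster_genesets(CorrelationMatrix(rho), k=4)
        assert labels.nunique() == 4

    def test_k_too_large_rejected(self):
        rho = pd.DataFrame(np.eye(3), index=list("abc"), columns=["PC1", "PC2", "PC3"])
        with pytest.raises(ValueError, match="exceeds"):
            cluster_genesets(CorrelationMatrix(rho), k=5)

    def test_immune_and_decoy_fixture_sets_separate(self, discovery_result):
        from umiskit.synthetic import IMMUNE_FIXTURE_SET_NAMES

        labels = cluster_genesets(discovery_result.correlations, k=2)
        immune_labels = set(labels[IMMUNE_FIXTURE_SET_NAMES])
        assert len(immune_labels) == 1


class TestIdentifyImmuneAxis:
    def test_pattern_like_published_correlation_matrix(self):
        # Immune sets near zero on PC1/PC3 and mean -0.32 on PC2 pick the
        # negative aspect of PC2.
        rho = pd.DataFrame(
            {
                "PC1": [0.02, -0.05, 0.01],
                "PC2": [-0.30, -0.35, -0.31],
                "PC3": [0.03, 0.00, -0.04],
            },
            index=["IFN_G", "IFN_A", "ALLO"],
        )
        pc, direction, _ = identify_immune_axis(
            CorrelationMatrix(rho), ["IFN_G", "IFN_A", "ALLO"]
        )
        assert (pc, direction) == (2, "negative")

    def test_single_dominant_positive_axis(self):
        rho = pd.DataFrame({"PC1": [0.9], "PC2": [0.1], "PC3": [0.0]}, index=["S"])
        pc, direction, exclusivity = identify_immune_axis(CorrelationMatrix(rho), ["S"])
        assert (pc, direction) == (1, "positive")
        assert exclusivity == pytest.approx(9.0)

    def test_tie_breaks_to_lower_pc(self):
        rho = pd.DataFrame({"PC1": [0.5], "PC2": [-0.5]}, index=["S"])
        pc, direction, _ = identify_immune_axis(CorrelationMatrix(rho), ["S"])
        assert (pc, direction) == (1, "positive")

    def test_all_zero_rejected(self):
        rho = pd.DataFrame({"PC1": [0.0], "PC2": [0.0]}, index=["S"])
        with pytest.raises(ValueError, match="no immune axis"):
            identify_immune_axis(CorrelationMatrix(rho), ["S"])


class TestSelectSignature:
    def _pca(self, loadings_pc1):
        from umiskit.discovery import PcaResult

        genes = [f"g{i}" for i in range(len(loadings_pc1))]
        loadings = pd.DataFrame({"PC1": loadings_pc1}, index=genes)
        scores = pd.DataFrame({"PC1": [0.0]}, index=["s"])
        return PcaResult(scores, loadings, np.array([1.0]))

    def test_negative_sign_filter(self):
        pca = self._pca([-0.5, 0.1, -0.2, 0.3])
        assert select_signature(pca, 1, "negative").gene_ids == ["g0", "g2"]

    def test_positive_is_complement_without_zeros(self):
        pca = self._pca([-0.5, 0.1, -0.2, 0.3, 0.0])
        assert select_signature(pca, 1, "positive").gene_ids == ["g1", "g3"]
        pos = set(select_signature(pca, 1, "positive").gene_ids)
        neg = set(select_signature(pca, 1, "negative").gene_ids)
        assert pos | neg | {"g4"} == {f"g{i}" for i in range(5)}
        assert not pos & neg

    def test_sign_flip_invariance_of_selected_genes(self, discovery_result):
        # Flipping the PCA orientation flips the reported direction but
        # selects exactly the same genes.
        import copy

        pca = discovery_result.pca
        flipped = copy.deepcopy(pca)
        col = f"PC{discovery_result.immune_pc}"
        flipped.loadings[col] *= -1
        flipped.scores[col] *= -1
        opposite = {"positive": "negative", "negative": "positive"}[
            discovery_result.immune_direction
        ]
        sig_flipped = select_signature(flipped, discovery_result.immune_pc, opposite)
        assert set(sig_flipped.gene_ids) == set(discovery_result.signature.gene_ids)


class TestPipelineRecovery:
    def test_signature_jaccard_against_planted_program(self, discovery_result, normalized_cohort):
        _, _, truth = normalized_cohort
        selected = set(discovery_result.signature.gene_ids)
        planted = set(truth.immune_gene_ids) & set(discovery_result.top_variance_genes)
        jaccard = len(selected & planted) / len(selected | planted)
        assert jaccard >= 0.7

    def test_umis_tracks_latent_inflammation(self, umis_scores, normalized_cohort):
        _, _, truth = normalized_cohort
        rho = spearmanr(umis_scores, truth.theta.reindex(umis_scores.index)).statistic
        assert rho >= 0.9

    def test_candidate_pcs_capped_and_thresholded(self, discovery_result):
        pcs = candidate_pcs(discovery_result.pca)
        assert 1 <= len(pcs) <= 3
        for pc in pcs:
            assert discovery_result.pca.explained_variance_fraction[pc - 1] > 0.05
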