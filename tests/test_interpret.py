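"""Interpretation layer: attention records, PCRI and its normalization,
variable-gene ranking, clustering, dose-response."""

import itertools

import numpy as np
import pandas as pd
import pytest

from chromoformer import (
    Chromoformer,
    ModelConfig,
    annotate_pcres,
    cluster_pcri,
    compute_pcri,
    extract_attention,
    normalize_pcri,
    pcre_dose_response,
    rank_variable_genes,
)
from chromoformer.interpret import attention_tss_profile


@pytest.fixture(scope="module")
def toy_model():
    return Chromoformer(ModelConfig.scaled_down(seed=6))


class TestAttentionExtraction:
    def test_six_embedding_maps_per_gene(self, toy_model, toy_dataset):
        records = extract_attention(toy_model, toy_dataset.examples[0])
        emb = [r for r in records if r.module == "embedding"]
        assert len(emb) == 6  # 3 resolutions x 2 heads
        assert {r.resolution for r in emb} == set(toy_model.config.resolutions)

    def test_every_row_sums_to_one(self, toy_model, toy_dataset):
        ex = next(e for e in toy_dataset.examples if e.n_interactions > 0)
        records = extract_attention(toy_model, ex, include_pairwise=True, include_regulation=True)
        assert {r.module for r in records} == {"embedding", "pairwise", "regulation"}
        for r in records:
            if r.module == "regulation":
                # padded key columns carry zero weight; rows still sum to 1
                assert np.abs(r.weights.sum(axis=-1) - 1.0).max() < 1e-5
            else:
                assert np.abs(r.weights.sum(axis=-1) - 1.0).max() < 1e-5
            assert r.weights.min() >= 0.0

    def test_tss_profile_shapes(self, toy_model, toy_dataset):
        prof = attention_tss_profile(toy_model, toy_dataset.examples[0])
        for r, mat in prof.items():
            assert mat.shape == (2, toy_model.config.n_bins(r))


class TestComputePcri:
    def test_identical_embeddings_give_zero(self, rng):
        v = rng.normal(size=384)
        pcri, degenerate = compute_pcri(v, v.copy())
        assert pcri == 0.0 and not degenerate

    def test_two_dim_toy_matches_hand_arithmetic(self):
        # (1,-1) and (-1,1) standardize (sample sd = sqrt(2)) to
        # (1,-1)/sqrt(2) and (-1,1)/sqrt(2); distance = 2*sqrt(2)/sqrt(2) = 2
        pcri, _ = compute_pcri(np.array([1.0, -1.0]), np.array([-1.0, 1.0]))
        assert np.isclose(pcri, 2.0)

    def test_invariant_under_per_vector_affine_transforms(self, rng):
        u = rng.normal(size=96)
        v = rng.normal(size=96)
        ref, _ = compute_pcri(u, v)
        for _ in range(5):
            a, b = rng.uniform(0.1, 5.0, size=2)
            c, d = rng.normal(size=2) * 10
            got, _ = compute_pcri(a * u + c, b * v + d)
            assert np.isclose(got, ref)

    def test_zero_variance_vector_flagged_degenerate(self, rng):
        pcri, degenerate = compute_pcri(np.ones(10), rng.normal(size=10))
        assert degenerate and np.isnan(pcri)

    def test_length_mismatch_rejected(self, rng):
        from chromoformer import InputError

        with pytest.raises(InputError):
            compute_pcri(np.ones(4), np.ones(5))


class TestNormalizePcri:
    def table(self, values, cell="A"):
        return pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(len(values))], "cell_type": cell, "pcri": values}
        )

    def test_two_gene_z_scores(self):
        out = normalize_pcri(self.table([1.0, 3.0]))
        assert np.allclose(out["normalized_pcri"], [-1.0, 1.0])

    def test_idempotent_with_unit_moments_per_cell_type(self, rng):
        t = pd.concat([self.table(rng.gamma(2, 2, size=30), "A"),
                       self.table(rng.gamma(3, 1, size=20), "B")])
        once = normalize_pcri(t)
        for _, g in once.groupby("cell_type"):
            assert np.isclose(g["normalized_pcri"].mean(), 0.0)
            assert np.isclose(g["normalized_pcri"].std(ddof=0), 1.0)
        twice = normalize_pcri(once.drop(columns="pcri").rename(columns={"normalized_pcri": "pcri"}))
        np.testing.assert_allclose(twice["normalized_pcri"], once["normalized_pcri"])

    def test_constant_pcri_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="constant"):
            out = normalize_pcri(self.table([2.0, 2.0, 2.0]))
        assert np.all(out["normalized_pcri"] == 0.0)


class TestRankVariableGenes:
    def make_table(self):
        rows = []
        profiles = {"g_flat": [1.0, 1.0, 1.0], "g_mid": [0.0, 0.5, 1.0], "g_var": [-2.0, 0.0, 2.0]}
        for gid, vals in profiles.items():
            for ct, v in zip("ABC", vals):
                rows.append({"gene_id": gid, "cell_type": ct, "normalized_pcri": v})
        return pd.DataFrame(rows)

    def test_hand_computed_variance_ordering(self):
        ranked = rank_variable_genes(self.make_table(), top_n=3)
        assert ranked == ["g_var", "g_mid", "g_flat"]

    def test_constant_gene_ranks_last_and_top_n_caps(self):
        assert rank_variable_genes(self.make_table(), top_n=2) == ["g_var", "g_mid"]
        assert rank_variable_genes(self.make_table(), top_n=100)[-1] == "g_flat"

    def test_incomplete_gene_excluded_with_warning(self):
        t = self.make_table().iloc[:-1]  # drop one cell type of g_var
        with pytest.warns(UserWarning, match="missing"):
            ranked = rank_variable_genes(t, top_n=5)
        assert "g_var" not in ranked


def brute_force_average_linkage(m):
    """Tiny agglomeration oracle on rows of m with correlation distance."""
    n = m.shape[0]
    clusters = {i: [i] for i in range(n)}
    d = {}
    for i, j in itertools.combinations(range(n), 2):
        d[(i, j)] = 1 - np.corrcoef(m[i], m[j])[0, 1]
    merges = []
    nxt = n
    while len(clusters) > 1:
        (a, b), dist = min(
            (
                ((ka, kb), np.mean([d[tuple(sorted((i, j)))] for i in clusters[ka] for j in clusters[kb]]))
                for ka, kb in itertools.combinations(sorted(clusters), 2)
            ),
            key=lambda t: t[1],
        )
        merges.append((a, b, dist, len(clusters[a]) + len(clusters[b])))
        clusters[nxt] = clusters.pop(a) + clusters.pop(b)
        nxt += 1
    return merges


class TestClusterPcri:
    def test_identical_columns_merge_first_at_zero_distance(self, rng):
        base = rng.normal(size=6)
        m = pd.DataFrame(
            {"A": base, "B": base * 2 + 1e-9 * rng.normal(size=6), "C": rng.normal(size=6)},
            index=[f"g{i}" for i in range(6)],
        )
        out = cluster_pcri(m)
        link = out["cell_linkage"]
        assert {int(link[0, 0]), int(link[0, 1])} == {0, 1}
        assert link[0, 2] < 1e-6

    def test_anticorrelated_columns_have_distance_two(self, rng):
        x = rng.normal(size=8)
        m = pd.DataFrame({"A": x, "B": -x}, index=[f"g{i}" for i in range(8)])
        out = cluster_pcri(m)
        assert np.isclose(out["cell_linkage"][0, 2], 2.0)

    def test_linkage_matches_brute_force_oracle(self, rng):
        m = rng.normal(size=(4, 5))
        out = cluster_pcri(pd.DataFrame(m, index=list("wxyz"), columns=list("ABCDE")))
        oracle = brute_force_average_linkage(m)
        link = out["gene_linkage"]
        for k, (_, _, dist, size) in enumerate(oracle):
            assert np.isclose(link[k, 2], dist)
            assert link[k, 3] == size

    def test_zero_variance_row_excluded_with_warning(self, rng):
        m = pd.DataFrame(rng.normal(size=(4, 4)), index=list("wxyz"), columns=list("ABCD"))
        m.loc["w"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            out = cluster_pcri(m)
        assert "w" not in out["genes"]


class TestDoseResponse:
    def test_overlap_annotation_flags_correct_pcres(self):
        pcres = pd.DataFrame(
            {"gene_id": ["g1", "g1", "g2"], "chrom": ["chr1", "chr1", "chr2"],
             "start": [100, 500, 100], "end": [200, 600, 200]}
        )
        bed = pd.DataFrame({"chrom": ["chr1"], "start": [150], "end": [160]})
        out = annotate_pcres(pcres, bed)
        assert out["annotated"].tolist() == [True, False, False]

    def test_zero_count_group_present_and_medians_correct(self):
        preds = pd.DataFrame(
            {"gene_id": ["a", "b", "c", "d"], "pcri": [1.0, 2.0, 5.0, 7.0],
             "expression": [1.0, 1.0, 4.0, 8.0]}
        )
        ann = pd.DataFrame({"gene_id": ["c", "d", "d"], "annotated": [True, True, True]})
        summary, rho = pcre_dose_response(preds, ann)
        assert summary["n_annotated"].tolist() == [0, 1, 2]
        assert summary.loc[summary["n_annotated"] == 0, "median_pcri"].item() == 1.5
        assert rho > 0

    def test_empty_annotation_gives_single_zero_bin(self):
        preds = pd.DataFrame({"gene_id": ["a"], "pcri": [1.0]})
        summary, rho = pcre_dose_response(preds, pd.DataFrame(columns=["gene_id", "annotated"]))
        assert summary["n_annotated"].tolist() == [0]
        assert np.isnan(rho)
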