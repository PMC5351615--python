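"""Coverage-file reading, replicate merging, fragment methylation, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epidriver import (
    DataError,
    SampleMethylome,
    StudyDesign,
    cluster_samples,
    element_distribution,
    fragment_methylation,
    global_mean_methylation,
    merge_replicates,
    methylation_histogram,
    plan_methylation_states,
    read_coverage_file,
    replicate_correlation,
    simulate_counts,
)
from epidriver.methylome import linkage_to_newick
from epidriver.regions import GeneModel
from conftest import counts_frame, make_catalog


def sample_of(rows, sample_id="s", role="primary", pair_id="P1"):
    return SampleMethylome(sample_id, role, counts_frame(rows), pair_id)


class TestReadCoverageFile:
    def write(self, tmp_path, text):
        p = tmp_path / "x.cov"
        p.write_text(text)
        return p

    def test_coordinate_shift(self, tmp_path):
        p = self.write(tmp_path, "chr1\t11\t11\t100.0\t5\t0\n")
        m = read_coverage_file(p, "s", "primary")
        assert m.counts.iloc[0].tolist() == ["chr1", 10, 5, 0]

    def test_duplicate_positions_merge_additively(self, tmp_path):
        p = self.write(
            tmp_path, "chr1\t5\t5\t75.0\t3\t1\nchr1\t5\t5\t50.0\t2\t2\n"
        )
        m = read_coverage_file(p, "s", "primary")
        assert len(m.counts) == 1
        assert m.counts.iloc[0][["meth", "unmeth"]].tolist() == [5, 3]

    def test_percent_disagreement_rejected(self, tmp_path):
        p = self.write(tmp_path, "chr1\t5\t5\t50.0\t5\t0\n")
        with pytest.raises(DataError, match="percent"):
            read_coverage_file(p, "s", "primary")

    def test_negative_counts_rejected(self, tmp_path):
        p = self.write(tmp_path, "chr1\t5\t5\t100.0\t-5\t0\n")
        with pytest.raises(DataError, match="negative"):
            read_coverage_file(p, "s", "primary")

    def test_malformed_row_reports_line(self, tmp_path):
        p = self.write(tmp_path, "chr1\t5\t5\t100.0\t5\t0\nchr1\tfoo\t6\t0.0\t0\t1\n")
        with pytest.raises(DataError, match="line 2"):
            read_coverage_file(p, "s", "primary")

    def test_zero_coverage_row_rejected(self, tmp_path):
        p = self.write(tmp_path, "chr1\t5\t5\t0.0\t0\t0\n")
        with pytest.raises(DataError, match="zero-coverage"):
            read_coverage_file(p, "s", "primary")


class TestMergeReplicates:
    def test_counts_sum(self):
        a = sample_of([("c", 1, 5, 5)])
        b = sample_of([("c", 1, 5, 5)])
        m = merge_replicates(a, b)
        assert m.counts.iloc[0][["meth", "unmeth"]].tolist() == [10, 10]

    def test_union_of_positions(self):
        a = sample_of([("c", 1, 3, 1), ("c", 9, 2, 2)])
        b = sample_of([("c", 9, 1, 1)])
        m = merge_replicates(a, b)
        assert m.counts.set_index("pos").loc[1, ["meth", "unmeth"]].tolist() == [3, 1]
        assert m.counts.set_index("pos").loc[9, ["meth", "unmeth"]].tolist() == [3, 3]

    def test_mismatched_roles_error(self):
        a = sample_of([("c", 1, 1, 1)], role="primary")
        b = sample_of([("c", 1, 1, 1)], role="metastatic")
        with pytest.raises(DataError, match="metadata"):
            merge_replicates(a, b)

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 20), st.integers(0, 30), st.integers(0, 30)
            ),
            min_size=1,
            max_size=15,
            unique_by=lambda t: t[0],
        ),
        st.lists(
            st.tuples(
                st.integers(0, 20), st.integers(0, 30), st.integers(0, 30)
            ),
            min_size=1,
            max_size=15,
            unique_by=lambda t: t[0],
        ),
    )
    @settings(max_examples=50, deadline=None)
    def test_commutative(self, rows_a, rows_b):
        a = sample_of([("c", p, m, u) for p, m, u in rows_a])
        b = sample_of([("c", p, m, u) for p, m, u in rows_b])
        ab = merge_replicates(a, b).counts
        ba = merge_replicates(b, a).counts
        pd.testing.assert_frame_equal(ab, ba)


class TestReplicateCorrelation:
    def test_identical_samples(self):
        a = sample_of([("c", i, 10 + i, 10) for i in range(5)])
        r, n = replicate_correlation(a, a, cov_min=10)
        assert r == pytest.approx(1.0)
        assert n == 5

    def test_exact_anticorrelation(self):
        a = sample_of([("c", 0, 0, 10), ("c", 1, 5, 5), ("c", 2, 10, 0)])
        b = sample_of([("c", 0, 10, 0), ("c", 1, 5, 5), ("c", 2, 0, 10)])
        r, _ = replicate_correlation(a, b, cov_min=10)
        assert r == pytest.approx(-1.0)

    def test_too_few_common_sites(self):
        a = sample_of([("c", 0, 10, 0), ("c", 1, 10, 0)])
        with pytest.raises(DataError, match="common"):
            replicate_correlation(a, a)

    def test_simulated_replicates_highly_correlated(self, small_catalog, small_study):
        """Replicate libraries from one truth at coverage 30 give r >= 0.9."""
        design, truth, counts = small_study
        a = SampleMethylome("P1", "primary", counts["P1"], "P1")
        b = SampleMethylome("P1", "primary", counts["P1-rep2"], "P1")
        r, n = replicate_correlation(a, b, cov_min=10)
        assert r >= 0.9
        assert n > 100


class TestFragmentMethylation:
    @pytest.fixture()
    def catalog(self):
        return make_catalog([("c", 0, 50, [5, 10, 20]), ("c", 50, 100, [60, 70])])

    def test_coverage_gate(self, catalog):
        # first fragment: coverages 12, 11, 0-absent -> analysable with 2 sites
        # second fragment: coverages 12, 9 -> not analysable
        s = sample_of(
            [("c", 5, 6, 6), ("c", 10, 5, 6), ("c", 60, 6, 6), ("c", 70, 4, 5)]
        )
        table = fragment_methylation(s, catalog, cov_min=10, min_cpgs=2)
        assert table["fragment_id"].tolist() == ["c:0-50"]
        assert table.iloc[0]["n_cpgs_covered"] == 2

    def test_pooled_level_arithmetic(self, catalog):
        s = sample_of([("c", 60, 8, 2), ("c", 70, 6, 4)])
        table = fragment_methylation(s, catalog, cov_min=10, min_cpgs=2)
        assert table.iloc[0]["level"] == pytest.approx(14 / 20)

    def test_subthreshold_cpgs_still_pool(self, catalog):
        # gate passes on two sites >= 10; the third (cov 4) still pools
        s = sample_of([("c", 5, 10, 2), ("c", 10, 11, 1), ("c", 20, 4, 0)])
        table = fragment_methylation(s, catalog, cov_min=10, min_cpgs=2)
        row = table.iloc[0]
        assert row["pooled_meth"] == 25 and row["pooled_unmeth"] == 3
        assert row["n_cpgs_covered"] == 2

    def test_merged_replicates_pool_sums(self, small_catalog, small_study):
        design, truth, counts = small_study
        a = SampleMethylome("P1", "primary", counts["P1"], "P1")
        b = SampleMethylome("P1", "primary", counts["P1-rep2"], "P1")
        merged = merge_replicates(a, b)
        ta = fragment_methylation(a, small_catalog).set_index("fragment_id")
        tb = fragment_methylation(b, small_catalog).set_index("fragment_id")
        tm = fragment_methylation(merged, small_catalog).set_index("fragment_id")
        both = ta.index.intersection(tb.index)
        total = (
            ta.loc[both, "pooled_meth"] + tb.loc[both, "pooled_meth"]
        )
        assert (tm.loc[both, "pooled_meth"] == total).all()


class TestGlobalMean:
    def test_fully_methylated(self):
        s = sample_of([("c", i, 10, 0) for i in range(3)])
        assert global_mean_methylation(s) == pytest.approx(100.0)

    def test_balanced_extremes(self):
        s = sample_of([("c", 0, 10, 0), ("c", 1, 0, 10)])
        assert global_mean_methylation(s) == pytest.approx(50.0)

    def test_no_qualifying_cpgs_error(self):
        s = sample_of([("c", 0, 1, 1)])
        with pytest.raises(DataError):
            global_mean_methylation(s, cov_min=10)

    def test_uniform_truth_recovered(self, small_catalog):
        design = StudyDesign(n_pairs=1, include_normal=False, replicate_samples=(),
                             coverage_mean=50, dispersion=0.0,
                             meth_dispersion=0.0, seed=13)
        frag_ids = [f.id for f in small_catalog]
        from epidriver.simulate import TruthTable
        levels = pd.DataFrame(0.47, index=frag_ids, columns=["P1", "M1"])
        labels = pd.DataFrame({"fragment_id": frag_ids, "label": "background",
                               "direction": "", "delta_true": np.nan,
                               "pair_id": "", "pattern": ""})
        counts = simulate_counts(TruthTable(levels, labels), small_catalog, design)
        s = SampleMethylome("P1", "primary", counts["P1"], "P1")
        assert global_mean_methylation(s, cov_min=10) == pytest.approx(47.0, abs=1.0)


class TestHistogram:
    def test_all_zero_levels_in_first_bin(self):
        table = pd.DataFrame({"level": [0.0, 0.0, 0.0]})
        counts, edges = methylation_histogram(table)
        assert counts[0] == 3 and counts[1:].sum() == 0

    def test_counts_sum_to_fragments(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"level": rng.random(57)})
        counts, _ = methylation_histogram(table, n_bins=13)
        assert counts.sum() == 57

    def test_last_bin_closed(self):
        counts, _ = methylation_histogram(pd.DataFrame({"level": [1.0]}))
        assert counts[-1] == 1

    def test_empty_table_errors(self):
        with pytest.raises(DataError):
            methylation_histogram(pd.DataFrame({"level": []}))

    def test_bimodal_truth_shows_outer_modes(self, small_catalog, small_study):
        design, truth, counts = small_study
        s = SampleMethylome("P1", "primary", counts["P1"], "P1")
        table = fragment_methylation(s, small_catalog)
        h, _ = methylation_histogram(table, n_bins=20)
        outer = h[:4].sum() + h[-4:].sum()
        assert outer > 0.6 * h.sum()


class TestClustering:
    def test_identical_samples_merge_first(self):
        rng = np.random.default_rng(1)
        rows = [("c", i, int(m), 20 - int(m)) for i, m in
                enumerate(rng.integers(0, 21, size=30))]
        rows2 = [("c", i, int(m), 20 - int(m)) for i, m in
                 enumerate(rng.integers(0, 21, size=30))]
        a = sample_of(rows, sample_id="a")
        b = sample_of(rows, sample_id="b")
        c = sample_of(rows2, sample_id="c")
        link, labels = cluster_samples([c, a, b], cov_min=10)
        assert labels == ["a", "b", "c"]
        first = sorted(link[0, :2].astype(int))
        assert [labels[i] for i in first] == ["a", "b"]
        assert link[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_two_samples_single_merge(self):
        a = sample_of([("c", i, 20 - i * 4, i * 4) for i in range(5)], sample_id="a")
        b = sample_of([("c", i, i * 4, 20 - i * 4) for i in range(5)], sample_id="b")
        link, labels = cluster_samples([a, b])
        assert link.shape == (1, 4)

    def test_constant_profile_rejected(self):
        a = sample_of([("c", i, 10, 10) for i in range(5)], sample_id="a")
        b = sample_of([("c", i, i * 4, 20 - i * 4) for i in range(5)], sample_id="b")
        with pytest.raises(DataError, match="constant"):
            cluster_samples([a, b])

    def test_pairs_cluster_together(self, small_catalog):
        """Each primary joins its own metastatic partner before any other sample.

        Uses a background-only study so the pair-specific baselines are the
        only structure (planted DMFs in a tiny genome would be an
        unrealistically large fraction of fragments and dominate).
        """
        from epidriver import plan_methylation_states, simulate_counts

        design = StudyDesign(n_pairs=2, coverage_mean=30, seed=21)
        truth = plan_methylation_states(small_catalog, design)
        counts = simulate_counts(truth, small_catalog, design)
        samples = [
            SampleMethylome(sid, "primary" if sid.startswith("P") else
                            ("normal" if sid == "normal" else "metastatic"),
                            counts[sid],
                            None if sid == "normal" else "P" + sid[1:])
            for sid in ["normal", "P1", "M1", "P2", "M2"]
        ]
        link, labels = cluster_samples(samples, cov_min=10)
        n = len(labels)
        members = {i: {labels[i]} for i in range(n)}
        first_partner = {}
        for k, (i, j, _, _) in enumerate(link[:, :4].astype(int)):
            merged = members[i] | members[j]
            members[n + k] = merged
            for s in members[i]:
                for t in members[j]:
                    first_partner.setdefault(s, {}).setdefault(t, k)
                    first_partner.setdefault(t, {}).setdefault(s, k)
        for p, m in (("P1", "M1"), ("P2", "M2")):
            partners = first_partner[p]
            assert min(partners, key=partners.get) == m

    def test_too_few_common_cpgs_error(self):
        a = sample_of([("c", 0, 10, 0)], sample_id="a")
        b = sample_of([("c", 5, 10, 0)], sample_id="b")
        with pytest.raises(DataError):
            cluster_samples([a, b])

    def test_newick_rendering(self):
        a = sample_of([("c", i, 20 - i * 4, i * 4) for i in range(5)], sample_id="a")
        b = sample_of([("c", i, i * 4, 20 - i * 4) for i in range(5)], sample_id="b")
        link, labels = cluster_samples([a, b])
        nwk = linkage_to_newick(link, labels)
        assert nwk.startswith("(") and nwk.endswith(";")
        assert "a" in nwk and "b" in nwk


class TestElementDistribution:
    def test_no_genes_all_intergenic(self):
        s = sample_of([("c", i, 10, 0) for i in range(5)])
        out = element_distribution(s, [])
        assert out["element"].tolist() == ["intergenic"]
        assert out.iloc[0]["n_cpgs"] == 5

    def test_promoter_precedence_over_body(self):
        # CpG at 1000 sits in geneA's promoter window and inside geneB's body
        genes = [
            GeneModel("A", "c", 1500, 3000, "+"),
            GeneModel("B", "c", 500, 2000, "+"),
        ]
        s = sample_of([("c", 1000, 10, 0)])
        out = element_distribution(s, genes)
        assert out["element"].tolist() == ["promoter"]

    def test_class_means(self):
        genes = [GeneModel("A", "c", 100, 200, "+")]
        s = sample_of([("c", 150, 10, 0), ("c", 5000, 0, 10)])
        out = element_distribution(s, genes, promoter_upstream=10,
                                   promoter_downstream=10)
        by = out.set_index("element")["mean_level"]
        assert by["gene_body"] == pytest.approx(1.0)
        assert by["intergenic"] == pytest.approx(0.0)
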