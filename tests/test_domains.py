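import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chromstate import (
    GenomeLayout,
    GeneModel,
    bh_fdr,
    classify_domain_context,
    context_fractions,
    merge_windows,
    partition_genome,
    peak_width_stats,
    window_enrichment,
)
from scipy import stats
from tests.conftest import make_track


def poisson_upper_tail_oracle(k, lam):
    """P(X >= k) by direct series summation of the complement."""
    if k <= 0:
        return 1.0
    acc = 0.0
    term = math.exp(-lam)
    for i in range(k):
        acc += term
        term *= lam / (i + 1)
    return 1.0 - acc


def bh_stepup_oracle(p):
    """Independent BH step-up: q_i = min_{j>=i} p_(j) * n / j."""
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [0.0] * n
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * n / rank)
        q[i] = prev
    return q


class TestPoissonWindowTest:
    def test_zero_count_gives_p_one(self):
        assert stats.poisson.sf(-1, 2.0) == 1.0

    @pytest.mark.parametrize("k,lam", [(10, 2.0), (3, 5.0), (1, 0.5), (40, 10.0)])
    def test_matches_series_summation(self, k, lam):
        assert stats.poisson.sf(k - 1, lam) == pytest.approx(
            poisson_upper_tail_oracle(k, lam), abs=1e-12)

    def test_p_monotone_decreasing_in_k(self):
        ps = [stats.poisson.sf(k - 1, 3.0) for k in range(0, 30)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_window_enrichment_detects_spike(self, layout):
        rng = np.random.default_rng(0)
        bg = [(int(p), "+") for p in rng.integers(0, 100_000, 2000)]
        spike = [(int(p), "+") for p in rng.integers(30_000, 31_000, 300)]
        chip = make_track(layout, {"chr1": bg + spike})
        ctrl = make_track(layout, {"chr1": [(int(p), "+") for p in
                                            rng.integers(0, 100_000, 2000)]})
        tests = window_enrichment(chip, ctrl, window=1000, step=1000)
        tests["q_value"] = bh_fdr(tests["p_value"])
        hits = tests[tests["q_value"] < 0.05]
        assert set(hits["start"]) == {30_000}

    def test_library_doubling_preserves_p_ranking(self, layout):
        """Uniformly doubling both libraries leaves the enrichment ranking
        essentially unchanged (exact order can swap between near-tied
        windows because the Poisson tail is nonlinear in counts)."""
        from scipy.stats import spearmanr

        rng = np.random.default_rng(2)
        chip_tags = [(int(p), "+") for p in rng.integers(0, 100_000, 3000)]
        ctrl_tags = [(int(p), "+") for p in rng.integers(0, 100_000, 1000)]
        t1 = window_enrichment(make_track(layout, {"chr1": chip_tags}),
                               make_track(layout, {"chr1": ctrl_tags}),
                               window=1000, step=1000)
        t2 = window_enrichment(make_track(layout, {"chr1": chip_tags * 2}),
                               make_track(layout, {"chr1": ctrl_tags * 2}),
                               window=1000, step=1000)
        rho = spearmanr(t1["p_value"], t2["p_value"]).statistic
        assert rho > 0.95


class TestBhFdr:
    def test_hand_worked_stepup(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]).tolist() == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3]).tolist() == [0.3]

    def test_all_zeros(self):
        assert bh_fdr([0.0, 0.0]).tolist() == [0.0, 0.0]

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_matches_independent_stepup_oracle(self, p):
        assert bh_fdr(p).tolist() == pytest.approx(bh_stepup_oracle(p))


class TestMergeWindows:
    def windows(self, triples):
        return pd.DataFrame(
            [("chr1", s, e, q) for s, e, q in triples],
            columns=["chrom", "start", "end", "q_value"])

    def test_gap_200_keeps_two_domains(self):
        dom = merge_windows(self.windows([(100, 200, .01), (200, 300, .01),
                                          (600, 700, .01)]), max_gap=200)
        assert list(zip(dom["start"], dom["end"])) == [(100, 300), (600, 700)]

    def test_gap_300_merges_all(self):
        dom = merge_windows(self.windows([(100, 200, .01), (200, 300, .01),
                                          (600, 700, .01)]), max_gap=300)
        assert list(zip(dom["start"], dom["end"])) == [(100, 700)]

    def test_empty_input(self):
        assert len(merge_windows(self.windows([]), max_gap=100)) == 0

    def test_domain_score_is_best_window(self):
        dom = merge_windows(self.windows([(0, 100, 1e-4), (100, 200, 1e-8)]),
                            max_gap=0)
        assert dom["score"].iloc[0] == pytest.approx(8.0)


class TestPeakWidthStats:
    def test_counting_fraction(self):
        dom = pd.DataFrame({"chrom": "chr1", "start": [0, 0, 0],
                            "end": [600, 800, 2000]})
        s = peak_width_stats(dom)
        assert s["fraction_in_range"] == pytest.approx(2 / 3)
        assert s["median_width"] == 800

    def test_single_domain_median(self):
        dom = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [500]})
        assert peak_width_stats(dom)["median_width"] == 500

    def test_empty_gives_nan_and_zero_n(self):
        s = peak_width_stats(pd.DataFrame(columns=["chrom", "start", "end"]))
        assert s["n"] == 0 and math.isnan(s["median_width"])


class TestContext:
    @pytest.fixture
    def partition(self, layout):
        # gA: +, tss 10000; window [8000, 12000); body remainder [12000, 16000)
        genes = [GeneModel("gA", "chr1", "+", 10_000, 16_000)]
        return partition_genome(genes, layout, flank=2000)

    def domains(self, pairs):
        return pd.DataFrame([("chr1", s, e, "H3K27me3", 5.0) for s, e in pairs],
                            columns=["chrom", "start", "end", "mark", "score"])

    def test_inside_gene_body_is_genic(self, partition):
        out = classify_domain_context(self.domains([(13_000, 14_000)]), partition)
        assert out["context"].iloc[0] == "genic"

    def test_zero_gene_overlap_is_intergenic(self, partition):
        out = classify_domain_context(self.domains([(50_000, 51_000)]), partition)
        assert out["context"].iloc[0] == "intergenic"

    def test_straddle_assigned_by_maximal_overlap(self, partition):
        # 1500 bp in the TSS window vs 500 bp genic -> tss_proximal;
        # 500 bp in window vs 1500 bp genic -> genic
        out = classify_domain_context(
            self.domains([(10_500, 12_500), (11_500, 13_500)]), partition)
        assert out["context"].tolist() == ["tss_proximal", "genic"]

    def test_gene_touching_domain_never_intergenic(self, partition):
        # mostly intergenic bp but 100 bp of gene body -> genic, not intergenic
        out = classify_domain_context(self.domains([(15_900, 20_000)]), partition)
        assert out["context"].iloc[0] == "genic"

    def test_fraction_table(self, partition):
        out = classify_domain_context(
            self.domains([(9_000, 9_500), (13_000, 13_500), (40_000, 40_500),
                          (41_000, 41_500)]), partition)
        frac = context_fractions(out)
        assert frac["intergenic"] == pytest.approx(0.5)
        assert frac.sum() == pytest.approx(1.0)
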