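import json

import numpy as np
import pandas as pd
import pytest

from chromstate import (
    GeneratorConfig,
    GeneModel,
    GenomeLayout,
    gained_mark_genes,
    gene_body_coverage,
    generate_dataset,
    locus_mosaic,
    lost_mark_genes,
    run_pipeline,
    tss_intensity_fold_change,
)
from tests.conftest import make_track


def tss_table(rows):
    return pd.DataFrame(rows, columns=["chrom", "strand", "tss"],
                        index=pd.Index([f"g{i}" for i in range(len(rows))],
                                       name="gene_id"))


class TestFoldChange:
    def test_identical_tracks_fold_one(self, layout):
        rng = np.random.default_rng(0)
        tags = [(int(p), "+") for p in rng.integers(0, 100_000, 5000)]
        chip = make_track(layout, {"chr1": tags})
        inp = make_track(layout, {"chr1": tags[:2000]})
        tt = tss_table([("chr1", "+", 20_000), ("chr1", "+", 60_000)])
        fc = tss_intensity_fold_change(chip, chip, tt, input_young=inp,
                                       input_old=inp)
        assert fc.global_fold == pytest.approx(1.0)
        assert np.allclose(fc.per_gene["fold"], 1.0)

    def test_doubled_signal_with_stable_input_doubles_fold(self, layout):
        rng = np.random.default_rng(1)
        young = [(int(p), "+") for p in rng.integers(19_000, 21_000, 2000)]
        old = [(int(p), "+") for p in rng.integers(19_000, 21_000, 4000)]
        inp = [(int(p), "+") for p in rng.integers(0, 100_000, 3000)]
        tt = tss_table([("chr1", "+", 20_000)])
        fc = tss_intensity_fold_change(
            make_track(layout, {"chr1": young}), make_track(layout, {"chr1": old}),
            tt, input_young=make_track(layout, {"chr1": inp}),
            input_old=make_track(layout, {"chr1": inp}))
        assert fc.global_fold == pytest.approx(2.0, rel=0.1)

    def test_library_normalization_cancels_global_change(self, layout):
        """Per-library scaling hides a uniform amplification by design."""
        rng = np.random.default_rng(2)
        young = [(int(p), "+") for p in rng.integers(19_000, 21_000, 2000)]
        old = young * 2
        tt = tss_table([("chr1", "+", 20_000)])
        fc = tss_intensity_fold_change(
            make_track(layout, {"chr1": young}),
            make_track(layout, {"chr1": old}, library_size=4000),
            tt, normalization="library")
        assert fc.global_fold == pytest.approx(1.0)

    def test_input_mode_requires_inputs(self, layout):
        t = make_track(layout, {"chr1": [(10, "+")]})
        with pytest.raises(ValueError, match="input"):
            tss_intensity_fold_change(t, t, tss_table([("chr1", "+", 100)]))


class TestGainedGenes:
    def flags(self, values):
        return pd.DataFrame({"H3K27me3": values},
                            index=pd.Index([f"g{i}" for i in range(len(values))],
                                           name="gene_id"))

    def test_identical_calls_empty(self):
        f = self.flags([True, False, True])
        assert gained_mark_genes(f, f.copy(), "H3K27me3") == []

    def test_constructed_gain(self):
        young = self.flags([False, False, True, False])
        old = self.flags([True, False, True, True])
        assert gained_mark_genes(young, old, "H3K27me3") == ["g0", "g3"]
        assert lost_mark_genes(young, old, "H3K27me3") == []


class TestLocusMosaic:
    def locus_genes(self, n=4):
        return [GeneModel(f"g{i}", "chr1", "+", 10_000 * (i + 1),
                          10_000 * (i + 1) + 5000, flags={"hoxish"})
                for i in range(n)]

    def calls(self, states):
        return pd.DataFrame({"state": states},
                            index=pd.Index([f"g{i}" for i in range(len(states))],
                                           name="gene_id"))

    def test_all_bivalent(self):
        m = locus_mosaic(self.locus_genes(), self.calls(["BIVALENT"] * 4), "hoxish")
        assert m.states == "BBBB"

    def test_ends_bivalent_centre_k4(self):
        m = locus_mosaic(self.locus_genes(),
                         self.calls(["BIVALENT", "K4_ONLY", "K4_ONLY", "BIVALENT"]),
                         "hoxish")
        assert m.states == "BKKB"

    def test_single_gene_locus(self):
        m = locus_mosaic(self.locus_genes(1), self.calls(["K27_ONLY"]), "hoxish")
        assert m.states == "R"

    def test_reverse_order(self):
        m = locus_mosaic(self.locus_genes(3),
                         self.calls(["K4_ONLY", "BIVALENT", "NONE"]),
                         "hoxish", reverse=True)
        assert m.states == "NBK" and m.gene_ids == ["g2", "g1", "g0"]

    def test_unknown_flag_errors(self):
        with pytest.raises(ValueError, match="locus flag"):
            locus_mosaic(self.locus_genes(), self.calls(["NONE"] * 4), "nope")


class TestGeneBodyCoverage:
    def gene(self):
        return [GeneModel("g", "chr1", "+", 10_000, 20_000)]

    def test_zero_tags_fraction_zero(self, layout):
        cov = gene_body_coverage(make_track(layout, {}), self.gene())
        assert cov.loc["g", "covered_fraction"] == 0.0

    def test_dense_coverage_fraction_one(self, layout):
        tags = [(p, "+") for p in range(10_000, 20_000, 40)]
        cov = gene_body_coverage(make_track(layout, {"chr1": tags}), self.gene())
        assert cov.loc["g", "covered_fraction"] == 1.0

    def test_half_covered_gene(self, layout):
        tags = [(p, "+") for p in range(10_000, 15_000, 40)]
        cov = gene_body_coverage(make_track(layout, {"chr1": tags}), self.gene())
        # fragment extension smears coverage ~200 bp past the last tag
        assert cov.loc["g", "covered_fraction"] == pytest.approx(0.5, abs=0.03)


@pytest.fixture(scope="module")
def dataset(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("synth")
    cfg = GeneratorConfig(seed=11, n_genes=40, n_chroms=1, chrom_length=600_000,
                          depth=120_000, k27_rate=1.0, n_histone=4,
                          n_intergenic_domains=5)
    manifest = generate_dataset(cfg, outdir)
    return manifest


def pipeline_config(manifest, conditions=("young", "old")):
    cfg = {
        "chrom_sizes": manifest["chrom_sizes"],
        "genes": manifest["genes"],
        "conditions": {c: manifest["tags"][c] for c in conditions},
        "expression": manifest["expression"],
    }
    if "old" in conditions:
        cfg["young"], cfg["old"] = "young", "old"
    return cfg


class TestRunPipeline:
    def test_smoke_summary_has_all_sections(self, dataset, tmp_path):
        summary = run_pipeline(pipeline_config(dataset), outdir=tmp_path)
        assert set(summary["conditions"]) == {"young", "old"}
        for key in ("transitions", "aging", "expression_by_state"):
            assert key in summary
        assert (tmp_path / "summary.json").exists()
        assert summary["aging"]["H3K27me3_global_fold"] > 1.5

    def test_rerun_is_byte_identical(self, dataset, tmp_path):
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        run_pipeline(pipeline_config(dataset), outdir=d1)
        run_pipeline(pipeline_config(dataset), outdir=d2)
        assert (d1 / "summary.json").read_bytes() == (d2 / "summary.json").read_bytes()

    def test_single_condition_omits_aging_sections(self, dataset, tmp_path):
        summary = run_pipeline(pipeline_config(dataset, conditions=("young",)),
                               outdir=tmp_path)
        assert "aging" not in summary and "transitions" not in summary

    def test_missing_input_fails_fast(self, dataset):
        cfg = pipeline_config(dataset)
        cfg["genes"] = "/nonexistent/genes.bed"
        with pytest.raises(FileNotFoundError, match="missing input"):
            run_pipeline(cfg)
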