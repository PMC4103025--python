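"""Seeded synthetic ChIP-seq data with known per-gene chromatin states.

The generator lays genes out one per fixed-size slot (TSS at the slot
centre) so that no gene's enrichment geometry reaches a neighbour's TSS
window, assigns each gene one of the four TSS states, couples expression to
state, and draws tags from a Poisson point process: a uniform background
everywhere plus a mark-specific rate over each gene's enriched region.
Enrichment geometry follows the field's canonical shapes: sharp H3K4me3 at
the TSS (+/- 500 bp), broad low-amplitude H3K27me3 (+/- 5 kb), H3K36me3
uniform over the bodies of expressed genes.

Library sizes are an *outcome* of the rates, not fixed: an IP against a
more abundant epitope yields proportionally more tags. This is the
calibrated-ChIP world in which a genome-wide change of a mark is measurable
at all; see the aging transform, which multiplies all H3K27me3 rates,
switches histone-flagged genes to BIVALENT and plants novel 0.5-1 kb
intergenic H3K27me3 domains.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genome import GenomeLayout, GeneModel, canonical_tss, partition_genome, DEFAULT_TSS_FLANK
from .coverage import TagTrack

MARKS = ("H3K4me3", "H3K27me3", "H3K36me3", "INPUT")
STATES = ("K4_ONLY", "K27_ONLY", "BIVALENT", "NONE")
READ_LENGTH = 36

# deterministic sub-stream ids for seed derivation
_STREAMS = {"genome": 1, "aging": 2, "expression": 3,
            "H3K4me3": 11, "H3K27me3": 12, "H3K36me3": 13, "INPUT": 14}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic genome.

    ``depth`` is the expected background (input) library size; the uniform
    background rate is depth / genome length, and mark libraries exceed it
    by their enrichment mass. Rates are expected tags per bp *above*
    background inside the enriched region.
    """

    seed: int
    n_genes: int = 1000
    n_chroms: int = 5
    chrom_length: int = 2_000_000
    slot_length: int = 10_000
    state_proportions: dict = field(default_factory=lambda: {
        "K4_ONLY": 0.40, "BIVALENT": 0.25, "K27_ONLY": 0.20, "NONE": 0.15,
    })
    depth: int = 2_000_000
    k4_rate: float = 2.0
    k27_rate: float = 0.5
    k36_rate: float = 0.5
    k4_halfspan: int = 500
    k27_halfspan: int = 5000
    gene_length_range: tuple = (4000, 7000)
    # expression model (log2 intensity)
    expr_means: dict = field(default_factory=lambda: {
        "K4_ONLY": 8.0, "BIVALENT": 3.0, "K27_ONLY": 2.5, "NONE": 2.0,
    })
    expr_sd: float = 1.0
    detection_level: float = 6.0
    noise_sd: float = 0.05
    # flagged gene groups
    n_histone: int = 20
    locus_label: str = "locusA"
    locus_size: int = 8
    # aging block
    aging_multiplier_k27: float = 4.0
    n_intergenic_domains: int = 50
    intergenic_width_range: tuple = (500, 1000)
    intergenic_rate_factor: float = 2.0   # x (k27_rate * multiplier)
    histone_reduction: float = 0.5        # linear expression factor with age

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        total = sum(self.state_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("state proportions must sum to 1")
        unknown = set(self.state_proportions) - set(STATES)
        if unknown:
            raise ValueError(f"unknown states in proportions: {unknown}")

    @property
    def genome_length(self) -> int:
        return self.n_chroms * self.chrom_length

    @property
    def background_rate(self) -> float:
        return self.depth / self.genome_length


def aging_study_config(seed: int) -> GeneratorConfig:
    """Conditions for the young-vs-old comparison.

    A lower background (input depth 5e5 on 10 Mb, 0.05 tags/bp) with a
    stronger H3K27me3 rate keeps TSS windows signal-dominated, which a
    fold-change estimate needs: window background that is common to both
    ages dilutes the measured fold toward 1. Half the gene slots are left
    empty so novel aged intergenic domains have enrichment-free space to
    land in (see docs/methods.md).
    """
    return GeneratorConfig(seed=seed, n_genes=500, depth=500_000, k27_rate=1.0)


@dataclass
class SyntheticTruth:
    """Ground truth the generator draws from and recovery tests check
    against: per-gene state/rates/expression plus the global background and
    any aging additions."""

    layout: GenomeLayout
    genes: list[GeneModel]
    table: pd.DataFrame            # per-gene: state, rates, expr, flags
    background_rate: float
    config: GeneratorConfig
    aged: bool = False
    aging_multiplier_k27: float | None = None
    intergenic_k27_domains: list = field(default_factory=list)  # (chrom, s, e, rate)

    def gene_index(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    def tss_table(self) -> pd.DataFrame:
        return canonical_tss(self.genes)

    def enrichment_regions(self, mark: str) -> list[tuple[str, int, int, float]]:
        """(chrom, start, end, rate-above-background) regions for a mark."""
        if mark == "INPUT":
            return []
        if mark not in MARKS:
            raise ValueError(f"unknown mark {mark!r}")
        cfg = self.config
        regions = []
        tss = self.tss_table()
        for g in self.genes:
            row = self.table.loc[g.gene_id]
            t = int(tss.loc[g.gene_id, "tss"])
            length = self.layout.lengths[g.chrom]
            if mark == "H3K4me3" and row["k4_rate"] > 0:
                s, e = t - cfg.k4_halfspan, t + cfg.k4_halfspan
            elif mark == "H3K27me3" and row["k27_rate"] > 0:
                s, e = t - cfg.k27_halfspan, t + cfg.k27_halfspan
            elif mark == "H3K36me3" and row["k36_rate"] > 0:
                s, e = g.tx_start, g.tx_end
            else:
                continue
            rate = row[{"H3K4me3": "k4_rate", "H3K27me3": "k27_rate",
                        "H3K36me3": "k36_rate"}[mark]]
            regions.append((g.chrom, max(0, s), min(length, e), float(rate)))
        if mark == "H3K27me3":
            regions.extend(self.intergenic_k27_domains)
        return regions


def make_genome(config: GeneratorConfig):
    """Build (layout, genes, truth) for the configured study.

    Deterministic for a fixed seed. Genes occupy evenly spaced slots with
    the TSS at the slot centre; the gene body extends 3' along the gene's
    strand by U[gene_length_range] bp.
    """
    rng = np.random.default_rng([config.seed, _STREAMS["genome"]])
    layout = GenomeLayout({
        f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)
    })
    slots_per_chrom = config.chrom_length // config.slot_length
    n_slots = slots_per_chrom * config.n_chroms
    if config.n_genes > n_slots:
        raise ValueError(
            f"genome too small: {config.n_genes} genes but only {n_slots} slots"
        )
    # evenly spread occupied slots across the genome
    occupied = np.linspace(0, n_slots - 1, config.n_genes).round().astype(int)
    states = rng.choice(
        list(config.state_proportions), size=config.n_genes,
        p=list(config.state_proportions.values()),
    )
    strands = rng.choice(["+", "-"], size=config.n_genes)
    lengths = rng.integers(config.gene_length_range[0],
                           config.gene_length_range[1] + 1, size=config.n_genes)
    genes, rows = [], []
    for i, slot in enumerate(occupied):
        chrom = f"chr{slot // slots_per_chrom + 1}"
        slot_start = (slot % slots_per_chrom) * config.slot_length
        tss = slot_start + config.slot_length // 2
        L = int(lengths[i])
        if strands[i] == "+":
            s, e = tss, min(tss + L, config.chrom_length)
        else:
            s, e = max(0, tss - L + 1), tss + 1
        gid = f"gene{i:05d}"
        genes.append(GeneModel(gene_id=gid, chrom=chrom, strand=strands[i],
                               tx_start=int(s), tx_end=int(e)))
        rows.append(gid)
    table = pd.DataFrame(index=pd.Index(rows, name="gene_id"))
    table["state"] = states
    table["k4_rate"] = np.where(np.isin(states, ["K4_ONLY", "BIVALENT"]),
                                config.k4_rate, 0.0)
    table["k27_rate"] = np.where(np.isin(states, ["K27_ONLY", "BIVALENT"]),
                                 config.k27_rate, 0.0)
    mu = np.array([config.expr_means[s] for s in states], dtype=float)
    table["true_log2_expr"] = rng.normal(mu, config.expr_sd)
    # histone-flagged genes: active (K4-only) genes, robustly expressed
    table["histone"] = False
    k4_ids = table.index[table["state"] == "K4_ONLY"]
    if config.n_histone > len(k4_ids):
        raise ValueError("not enough K4_ONLY genes to flag as histone")
    if config.n_histone:
        chosen = rng.choice(k4_ids, size=config.n_histone, replace=False)
        table.loc[chosen, "histone"] = True
        table.loc[chosen, "true_log2_expr"] = rng.normal(9.0, 0.5, config.n_histone)
    # gene-body H3K36me3 on genes expressed above the median
    median = table["true_log2_expr"].median()
    table["k36_rate"] = np.where(table["true_log2_expr"] > median,
                                 config.k36_rate, 0.0)
    # a contiguous locus flag for mosaic reports
    table["locus"] = ""
    if config.locus_size:
        table.iloc[: config.locus_size, table.columns.get_loc("locus")] = config.locus_label
    for g in genes:
        row = table.loc[g.gene_id]
        if row["histone"]:
            g.flags.add("histone")
        if row["locus"]:
            g.flags.add(str(row["locus"]))
    truth = SyntheticTruth(layout=layout, genes=genes, table=table,
                           background_rate=config.background_rate, config=config)
    return layout, genes, truth


def apply_aging(truth: SyntheticTruth, config: GeneratorConfig | None = None) -> SyntheticTruth:
    """Aged copy of the truth: every H3K27me3 rate multiplied, histone-flagged
    genes switched to BIVALENT at the aged H3K27me3 rate, and novel disjoint
    intergenic H3K27me3 domains planted. The young truth is untouched."""
    cfg = config or truth.config
    aged = copy.deepcopy(truth)
    aged.aged = True
    aged.aging_multiplier_k27 = cfg.aging_multiplier_k27
    aged.table["k27_rate"] *= cfg.aging_multiplier_k27
    hist = aged.table["histone"]
    aged_rate = cfg.k27_rate * cfg.aging_multiplier_k27
    aged.table.loc[hist, "state"] = "BIVALENT"
    aged.table.loc[hist, "k27_rate"] = aged_rate
    aged.intergenic_k27_domains = _sample_intergenic_domains(truth, cfg)
    return aged


def _sample_intergenic_domains(truth: SyntheticTruth, cfg: GeneratorConfig,
                               margin: int = 2500) -> list:
    """Disjoint intervals ``margin`` bp away from every gene body, TSS
    window and H3K27me3 enrichment span, so the called peaks neither merge
    with gene-anchored domains nor classify as anything but intergenic."""
    if cfg.n_intergenic_domains == 0:
        return []
    from . import intervals as iv

    rng = np.random.default_rng([cfg.seed, _STREAMS["aging"]])
    lo, hi = cfg.intergenic_width_range
    exclusion: dict[str, list[tuple[int, int]]] = {c: [] for c in truth.layout.chroms}
    tss = truth.tss_table()
    half = max(DEFAULT_TSS_FLANK, cfg.k27_halfspan)
    for g in truth.genes:
        t = int(tss.loc[g.gene_id, "tss"])
        exclusion[g.chrom].append((g.tx_start, g.tx_end))
        exclusion[g.chrom].append((t - half, t + half))
    candidates = []
    for chrom, length in truth.layout.lengths.items():
        pairs = exclusion[chrom]
        excl = iv.clip(iv.merge(*zip(*pairs)), 0, length) if pairs else iv.empty()
        s, e = iv.complement(excl, length)
        for a, b in zip(s, e):
            if b - a >= hi + 2 * margin:
                candidates.append((chrom, int(a) + margin, int(b) - margin))
    if len(candidates) < cfg.n_intergenic_domains:
        raise ValueError("not enough intergenic space for requested domains")
    picks = rng.choice(len(candidates), size=cfg.n_intergenic_domains, replace=False)
    rate = cfg.k27_rate * cfg.aging_multiplier_k27 * cfg.intergenic_rate_factor
    domains = []
    for i in picks:
        chrom, a, b = candidates[i]
        width = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(a, b - width + 1))
        domains.append((chrom, start, start + width, float(rate)))
    return sorted(domains)


def simulate_chip(
    truth: SyntheticTruth,
    mark: str,
    condition: str | None = None,
    depth: int | None = None,
    seed: int | None = None,
) -> TagTrack:
    """Draw one tag library for a mark: Poisson background everywhere plus
    each enriched region's rate, strands uniform, sorted per chromosome.

    ``depth=None`` (default) uses the rates as absolute expected tags/bp so
    the library size reflects epitope abundance; an integer rescales all
    rates so the expected total equals ``depth``. ``condition`` is a
    bookkeeping label only. ``seed`` defaults to a stream derived from the
    config seed and the mark.
    """
    if mark not in MARKS:
        raise ValueError(f"unknown mark {mark!r}")
    if depth is not None and depth <= 0:
        raise ValueError("depth must be > 0")
    if seed is None:
        seed_key = [truth.config.seed, _STREAMS[mark], 1 if truth.aged else 0]
    else:
        seed_key = [seed]
    rng = np.random.default_rng(seed_key)
    regions = truth.enrichment_regions(mark)
    b = truth.background_rate
    expected = b * truth.layout.genome_length + sum(
        r * (e - s) for _, s, e, r in regions
    )
    scale = depth / expected if depth is not None else 1.0
    per_chrom_pos: dict[str, list[np.ndarray]] = {c: [] for c in truth.layout.chroms}
    for chrom, length in truth.layout.lengths.items():
        n_bg = rng.poisson(b * length * scale)
        per_chrom_pos[chrom].append(rng.integers(0, length, size=n_bg))
    for chrom, s, e, rate in regions:
        n = rng.poisson(rate * (e - s) * scale)
        per_chrom_pos[chrom].append(rng.integers(s, e, size=n))
    chroms = {}
    for chrom in truth.layout.chroms:
        pos = np.concatenate(per_chrom_pos[chrom]) if per_chrom_pos[chrom] else \
            np.empty(0, dtype=np.int64)
        strand = rng.choice(np.array([1, -1], dtype=np.int8), size=pos.size)
        chroms[chrom] = (pos.astype(np.int64), strand)
    return TagTrack.from_arrays(truth.layout, chroms)


def simulate_expression(
    truth: SyntheticTruth,
    conditions: list[str],
    noise_sd: float | None = None,
    seed: int | None = None,
    aged_conditions: set | tuple = (),
    condition_effects: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Gene x condition log2 intensities: truth + condition effect +
    N(0, noise_sd) noise. Conditions named in ``aged_conditions`` apply
    log2(histone_reduction) to histone-flagged genes."""
    cfg = truth.config
    noise_sd = cfg.noise_sd if noise_sd is None else noise_sd
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng([cfg.seed if seed is None else seed,
                                 _STREAMS["expression"]])
    base = truth.table["true_log2_expr"].to_numpy()
    hist = truth.table["histone"].to_numpy()
    out = {}
    for cond in conditions:
        effect = (condition_effects or {}).get(cond, 0.0)
        values = base + effect + rng.normal(0.0, noise_sd, size=base.size)
        if cond in aged_conditions:
            values = values + np.where(hist, np.log2(cfg.histone_reduction), 0.0)
        out[cond] = values
    df = pd.DataFrame(out, index=truth.table.index)
    return df


# ---------------------------------------------------------------------------
# writers

def write_chrom_sizes(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for chrom, length in layout.lengths.items():
            fh.write(f"{chrom}\t{length}\n")


def write_genes_bed(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.tx_start}\t{g.tx_end}\t{g.gene_id}\t0\t{g.strand}\n")


def write_tags_bed(track: TagTrack, path, read_length: int = READ_LENGTH) -> None:
    """Tags as BED6 36-mers (clipped at chromosome ends); the 5' position
    and strand round-trip through load_tags."""
    frames = []
    for chrom in track.layout.chroms:
        if chrom not in track.chroms:
            continue
        length = track.layout.lengths[chrom]
        pos, sgn = track.chroms[chrom]
        plus = sgn > 0
        starts = np.where(plus, pos, np.maximum(0, pos - read_length + 1))
        ends = np.where(plus, np.minimum(pos + read_length, length), pos + 1)
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends,
            "name": ".", "score": 0,
            "strand": np.where(plus, "+", "-"),
        }))
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "start", "end", "name", "score", "strand"])
    df.to_csv(path, sep="\t", header=False, index=False)


def write_truth_json(truth: SyntheticTruth, path) -> None:
    payload = {
        "background_rate": truth.background_rate,
        "aged": truth.aged,
        "aging_multiplier_k27": truth.aging_multiplier_k27,
        "intergenic_k27_domains": truth.intergenic_k27_domains,
        "config": asdict(truth.config),
        "genes": truth.table.reset_index().to_dict(orient="records"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=str)


def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    expr.index.name = "gene_id"
    expr.to_csv(path, sep="\t")


def generate_dataset(config: GeneratorConfig, outdir, conditions=("young", "old"),
                     marks=("H3K4me3", "H3K27me3", "H3K36me3", "INPUT")) -> dict:
    """Write a full synthetic study to ``outdir``: chrom.sizes, gene BED,
    truth JSON per condition, tag BEDs per condition x mark, expression TSV.
    Returns the manifest of written paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout, genes, truth = make_genome(config)
    truths = {"young": truth}
    if "old" in conditions:
        truths["old"] = apply_aging(truth, config)
    manifest: dict = {"chrom_sizes": str(outdir / "chrom.sizes"),
                      "genes": str(outdir / "genes.bed"),
                      "tags": {}, "truth": {}}
    write_chrom_sizes(layout, manifest["chrom_sizes"])
    write_genes_bed(genes, manifest["genes"])
    for cond in conditions:
        t = truths[cond]
        manifest["truth"][cond] = str(outdir / f"truth_{cond}.json")
        write_truth_json(t, manifest["truth"][cond])
        manifest["tags"][cond] = {}
        for mark in marks:
            track = simulate_chip(t, mark, condition=cond)
            p = outdir / f"tags_{cond}_{mark}.bed"
            write_tags_bed(track, p)
            manifest["tags"][cond][mark] = str(p)
    expr = simulate_expression(truth, list(conditions),
                               aged_conditions={"old"})
    manifest["expression"] = str(outdir / "expression.tsv")
    write_expression_tsv(expr, manifest["expression"])
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
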