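"""Young-vs-old chromatin comparison and pipeline orchestration.

The cross-age TSS intensity comparison supports two scalings. Per-mark
library scaling (tags per 10M of the mark's own library) is the usual
single-sample unit, but it cancels any genome-wide change of the mark: an
amplified signal inflates its own denominator. For young/old comparisons
the default is therefore to scale each age's ChIP counts by its matched
*input* library, which is unaffected by the mark's abundance and puts both
ages on a common per-cell-equivalent scale (the same reasoning that
motivates spike-in calibration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import TagTrack, tss_window_intensity, extend_and_bin, DEFAULT_EXTENSION
from .genome import GeneModel, DEFAULT_TSS_FLANK
from .states import STATE_LETTERS

PSEUDO_INTENSITY = 0.5


@dataclass
class FoldChangeResult:
    per_gene: pd.DataFrame      # young, old, fold (pseudo-intensity ratio)
    global_fold: float          # ratio of mean intensities, no pseudocount
    mark: str
    normalization: str


def tss_intensity_fold_change(
    tags_young: TagTrack,
    tags_old: TagTrack,
    tss_table: pd.DataFrame,
    flank: int = DEFAULT_TSS_FLANK,
    mark: str = "",
    eps: float = PSEUDO_INTENSITY,
    normalization: str = "input",
    input_young: TagTrack | None = None,
    input_old: TagTrack | None = None,
) -> FoldChangeResult:
    """Per-gene and global old/young TSS intensity fold change.

    normalization="input" scales each age by its matched input library
    (both inputs required); "library" scales each track by its own size.
    Per-gene folds use a pseudo-intensity ``eps`` on both sides; the global
    fold is the ratio of mean intensities with no pseudocount.
    """
    if normalization == "input":
        if input_young is None or input_old is None:
            raise ValueError("input normalization requires both input tracks")
        ref_young = input_young.library_size
        ref_old = input_old.library_size
    elif normalization == "library":
        ref_young = ref_old = None
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    young = tss_window_intensity(tags_young, tss_table, flank,
                                 reference_library_size=ref_young)
    old = tss_window_intensity(tags_old, tss_table, flank,
                               reference_library_size=ref_old)
    per_gene = pd.DataFrame({
        "young": young, "old": old,
        "fold": (old + eps) / (young + eps),
    })
    global_fold = float(old.mean() / young.mean()) if young.mean() > 0 else float("nan")
    return FoldChangeResult(per_gene=per_gene, global_fold=global_fold,
                            mark=mark, normalization=normalization)


def gained_mark_genes(flags_young: pd.DataFrame, flags_old: pd.DataFrame,
                      mark: str) -> list[str]:
    """Genes unmarked in young that carry the mark in old (shared genes)."""
    shared = flags_young.index.intersection(flags_old.index)
    y = flags_young.loc[shared, mark]
    o = flags_old.loc[shared, mark]
    return sorted(shared[(~y) & o])


def lost_mark_genes(flags_young: pd.DataFrame, flags_old: pd.DataFrame,
                    mark: str) -> list[str]:
    shared = flags_young.index.intersection(flags_old.index)
    y = flags_young.loc[shared, mark]
    o = flags_old.loc[shared, mark]
    return sorted(shared[y & (~o)])


@dataclass
class LocusMosaic:
    """Ordered per-gene states along a flagged locus, one letter per gene
    (K = K4-only, B = bivalent, R = K27-only, N = none)."""

    locus: str
    gene_ids: list[str]
    states: str

    def __post_init__(self):
        assert len(self.states) == len(self.gene_ids)


def locus_mosaic(genes: list[GeneModel], calls: pd.DataFrame, locus_flag: str,
                 reverse: bool = False) -> LocusMosaic:
    """Mosaic report for the genes flagged with ``locus_flag``, in genomic
    order (``reverse=True`` for the 3'->5' reading of a minus-strand
    cluster)."""
    members = [g for g in genes if locus_flag in g.flags]
    if not members:
        raise ValueError(f"no gene carries locus flag {locus_flag!r}")
    members.sort(key=lambda g: (g.chrom, g.tx_start), reverse=reverse)
    ids = [g.gene_id for g in members]
    letters = "".join(STATE_LETTERS[calls.loc[gid, "state"]] for gid in ids)
    return LocusMosaic(locus=locus_flag, gene_ids=ids, states=letters)


def gene_body_coverage(
    tags_k36: TagTrack,
    genes: list[GeneModel],
    bin_width: int = 50,
    extension: int = DEFAULT_EXTENSION,
) -> pd.DataFrame:
    """Per-gene fraction of gene-body bins with nonzero extended-fragment
    coverage, plus the mean normalized body intensity (per 10M per bin)."""
    if not genes:
        raise ValueError("genes must be non-empty")
    cov = extend_and_bin(tags_k36, bin_width=bin_width, extension=extension)
    factor = cov.normalization_factor
    rows = []
    for g in genes:
        arr = cov.counts[g.chrom]
        b0 = g.tx_start // bin_width
        b1 = (g.tx_end - 1) // bin_width + 1
        body = arr[b0:b1]
        frac = float(np.mean(body > 0)) if body.size else 0.0
        mean_int = float(body.mean() * factor) if body.size else 0.0
        rows.append((g.gene_id, frac, mean_int))
    return pd.DataFrame(rows, columns=["gene_id", "covered_fraction",
                                       "mean_intensity"]).set_index("gene_id")


# ---------------------------------------------------------------------------
# pipeline

def run_pipeline(config: dict, outdir=None) -> dict:
    """End-to-end run from a config mapping (YAML-loadable):

    required keys: ``chrom_sizes``, ``genes`` (BED), ``conditions`` (mapping
    condition name -> {mark: tag BED, ..., INPUT: tag BED}); optional:
    ``expression`` (TSV), ``young``/``old`` (condition names for the aging
    section), ``params`` (flank, fdr, detection_level, window overrides).

    Validates every input path before computing anything, then runs
    load -> coverage -> domain calling -> state classification ->
    transitions -> expression integration -> aging comparison, writing
    tables under ``outdir`` when given. Returns the JSON-ready summary.
    """
    import json
    from pathlib import Path

    from .genome import read_chrom_sizes, load_gene_models, canonical_tss, partition_genome
    from .coverage import load_tags
    from .domains import (call_domains, classify_domain_context, context_fractions,
                          peak_width_stats)
    from .states import mark_presence, classify_states, state_counts, transition_table
    from .expression import read_expression_tsv, expression_by_state, fold_change_report

    # -- fail-fast validation
    for key in ("chrom_sizes", "genes", "conditions"):
        if key not in config:
            raise ValueError(f"config is missing required key {key!r}")
    paths = [config["chrom_sizes"], config["genes"]]
    for cond, marks in config["conditions"].items():
        if "INPUT" not in marks:
            raise ValueError(f"condition {cond!r} has no INPUT sample")
        paths.extend(marks.values())
    if config.get("expression"):
        paths.append(config["expression"])
    missing = [str(p) for p in paths if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")

    params = dict(config.get("params", {}))
    flank = int(params.get("flank", DEFAULT_TSS_FLANK))
    fdr = float(params.get("fdr", 0.05))
    detection = float(params.get("detection_level", 6.0))

    layout = read_chrom_sizes(config["chrom_sizes"])
    genes = load_gene_models(config["genes"], layout)
    tss = canonical_tss(genes)
    partition = partition_genome(genes, layout, flank=flank)

    summary: dict = {"parameters": {"flank": flank, "fdr": fdr,
                                    "detection_level": detection},
                     "n_genes": len(genes), "conditions": {}}
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    tracks: dict[str, dict[str, TagTrack]] = {}
    calls: dict[str, pd.DataFrame] = {}
    flags: dict[str, pd.DataFrame] = {}
    domains_all: dict[str, dict[str, pd.DataFrame]] = {}
    for cond, mark_paths in config["conditions"].items():
        tracks[cond] = {m: load_tags(p, layout) for m, p in mark_paths.items()}
        control = tracks[cond]["INPUT"]
        domains_all[cond] = {}
        cond_summary: dict = {"library_sizes": {
            m: t.library_size for m, t in tracks[cond].items()}}
        for mark, track in tracks[cond].items():
            if mark == "INPUT":
                continue
            dom = call_domains(track, control, mark, fdr=fdr)
            dom = classify_domain_context(dom, partition)
            domains_all[cond][mark] = dom
            cond_summary.setdefault("domains", {})[mark] = {
                "n": int(len(dom)),
                "context_fractions": context_fractions(dom).to_dict(),
                "width": {k: v for k, v in peak_width_stats(dom).items()
                          if k != "histogram"},
            }
            if outdir is not None:
                from .domains import write_domains_bed
                write_domains_bed(dom, outdir / f"domains_{cond}_{mark}.bed")
        state_marks = {m: domains_all[cond].get(m, pd.DataFrame(
            columns=["chrom", "start", "end", "mark", "score"]))
            for m in ("H3K4me3", "H3K27me3")}
        flags[cond] = mark_presence(state_marks, tss, flank=flank)
        calls[cond] = classify_states(flags[cond], condition=cond)
        cond_summary["state_counts"] = state_counts(calls[cond])["count"].to_dict()
        summary["conditions"][cond] = cond_summary
        if outdir is not None:
            calls[cond].to_csv(outdir / f"states_{cond}.tsv", sep="\t")

    cond_names = list(config["conditions"])
    if len(cond_names) >= 2:
        a, b = cond_names[0], cond_names[1]
        tt = transition_table(calls[a], calls[b])
        summary["transitions"] = {
            "from": a, "to": b,
            "table": tt.table.to_dict(),
            "retention": tt.retention.to_dict(),
            "n_shared": tt.n_shared,
        }
        if outdir is not None:
            tt.table.to_csv(outdir / f"transitions_{a}_{b}.tsv", sep="\t")

    expr = None
    if config.get("expression"):
        expr = read_expression_tsv(config["expression"])
        first = cond_names[0]
        if first in expr.columns:
            by_state = expression_by_state(expr, calls[first], first)
            summary["expression_by_state"] = {
                "condition": first,
                "summary": by_state["summary"].to_dict(),
                "bivalent_vs_all_p": by_state["bivalent_vs_all_p"],
            }

    young, old = config.get("young"), config.get("old")
    if young and old:
        aging: dict = {}
        for mark in ("H3K4me3", "H3K27me3"):
            if mark in tracks[young] and mark in tracks[old]:
                fc = tss_intensity_fold_change(
                    tracks[young][mark], tracks[old][mark], tss, flank=flank,
                    mark=mark, input_young=tracks[young]["INPUT"],
                    input_old=tracks[old]["INPUT"])
                aging[f"{mark}_global_fold"] = fc.global_fold
                gained = gained_mark_genes(flags[young], flags[old], mark)
                aging[f"{mark}_gained_genes"] = len(gained)
                if mark == "H3K27me3":
                    aging["gained_k27_gene_ids"] = gained
        for age in (young, old):
            dom = domains_all[age].get("H3K27me3")
            if dom is not None:
                aging[f"intergenic_k27_fraction_{age}"] = float(
                    context_fractions(dom).get("intergenic", 0.0))
        if expr is not None and young in expr.columns and old in expr.columns:
            fcr = fold_change_report(expr, young, old)
            aging["downregulated_over_40pct"] = int(fcr["flagged"].sum())
            gained = set(aging.get("gained_k27_gene_ids", []))
            not_expr = ((expr[young] < detection) & (expr[old] < detection))
            if gained:
                silent = [g for g in gained if g in expr.index and not_expr.get(g, False)]
                aging["gained_k27_not_expressed_fraction"] = len(silent) / len(gained)
        if "H3K36me3" in tracks[young]:
            body = gene_body_coverage(tracks[young]["H3K36me3"], genes)
            aging["mean_gene_body_k36_fraction"] = float(body["covered_fraction"].mean())
        summary["aging"] = aging

    if outdir is not None:
        summary["schema_version"] = 1
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, default=float)
    return summary
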