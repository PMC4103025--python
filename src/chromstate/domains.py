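"""Enriched-domain calling from ChIP vs input tag tracks.

Sliding windows are scored with an upper-tail Poisson test against a local
background rate: for each window the expected count is the maximum of the
library-scaled input count in the window, the library-scaled input count in
a surrounding 10 kb neighbourhood (rescaled to window size), and the
genome-wide ChIP expectation. The maximum guards against local biases that
a single genome-wide rate would miss. Window p-values are corrected with
Benjamini-Hochberg FDR; significant windows closer than ``max_gap`` merge
into domains scored by their best window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import intervals as iv
from .coverage import TagTrack
from .genome import GenomePartition

DEFAULT_FDR = 0.05
DEFAULT_LOCAL_SPAN = 10_000
PSEUDOCOUNT = 0.5

#: (window, step, max_gap) defaults per mark: sharp marks use small windows,
#: broad marks use wide ones.
MARK_WINDOW_PARAMS = {
    "H3K4me3": (200, 200, 200),
    "H3K27me3": (1000, 500, 1000),
    "H3K36me3": (1000, 500, 1000),
}


def _tag_counts_in_windows(track: TagTrack, chrom: str, ws, we) -> np.ndarray:
    """5'-position containment counts per window [ws, we)."""
    pos = track.positions(chrom)
    return np.searchsorted(pos, we, side="left") - np.searchsorted(pos, ws, side="left")


def window_enrichment(
    chip: TagTrack,
    control: TagTrack,
    window: int,
    step: int,
    local_span: int = DEFAULT_LOCAL_SPAN,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Tile each chromosome with windows and test ChIP counts against the
    local background. Returns a DataFrame with columns chrom, start, end,
    k_chip, lambda_bg, p_value (one row per window).
    """
    if chip.library_size == 0 or control.library_size == 0:
        raise ValueError("chip and input tracks must be non-empty")
    layout = chip.layout
    if layout.genome_length == 0:
        raise ValueError("zero-length genome")
    ratio = chip.library_size / control.library_size
    gw_rate = chip.library_size / layout.genome_length  # tags per bp
    frames = []
    for chrom, length in layout.lengths.items():
        if length < window:
            continue
        starts = np.arange(0, length - window + 1, step, dtype=np.int64)
        ends = starts + window
        k = _tag_counts_in_windows(chip, chrom, starts, ends)
        in_w = _tag_counts_in_windows(control, chrom, starts, ends)
        centers = starts + window // 2
        ls = np.clip(centers - local_span // 2, 0, length)
        le = np.clip(centers + local_span // 2, 0, length)
        in_local = _tag_counts_in_windows(control, chrom, ls, le)
        local_scale = window / np.maximum(le - ls, 1)
        lam = np.maximum.reduce([
            (in_w + pseudocount) * ratio,
            (in_local + pseudocount) * ratio * local_scale,
            np.full(starts.shape, gw_rate * window),
        ])
        p = stats.poisson.sf(k - 1, lam)
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends,
            "k_chip": k, "lambda_bg": lam, "p_value": p,
        }))
    return pd.concat(frames, ignore_index=True)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone-enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def merge_windows(significant: pd.DataFrame, max_gap: int, mark: str | None = None) -> pd.DataFrame:
    """Merge significant windows within ``max_gap`` bp into domains.

    ``significant`` needs columns chrom, start, end and a score column
    (q_value). Domain score = -log10 of the best window q.
    """
    cols = ["chrom", "start", "end", "mark", "score"]
    if len(significant) == 0:
        return pd.DataFrame(columns=cols)
    rows = []
    for chrom, sub in significant.groupby("chrom", sort=False):
        sub = sub.sort_values("start", kind="stable")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        qs = sub["q_value"].to_numpy()
        cur_s, cur_e, cur_q = starts[0], ends[0], qs[0]
        for s, e, q in zip(starts[1:], ends[1:], qs[1:]):
            if s <= cur_e + max_gap:
                cur_e = max(cur_e, e)
                cur_q = min(cur_q, q)
            else:
                rows.append((chrom, cur_s, cur_e, mark, _score(cur_q)))
                cur_s, cur_e, cur_q = s, e, q
        rows.append((chrom, cur_s, cur_e, mark, _score(cur_q)))
    return pd.DataFrame(rows, columns=cols)


def _score(q: float) -> float:
    return float(-np.log10(max(q, 1e-300)))


def call_domains(
    chip: TagTrack,
    control: TagTrack,
    mark: str,
    window: int | None = None,
    step: int | None = None,
    max_gap: int | None = None,
    fdr: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """Window test -> BH-FDR -> merge. Window geometry defaults to the
    per-mark values in ``MARK_WINDOW_PARAMS`` (200/200/200 for sharp marks,
    1000/500/1000 for broad ones)."""
    dw, ds, dg = MARK_WINDOW_PARAMS.get(mark, (1000, 500, 1000))
    window = window if window is not None else dw
    step = step if step is not None else ds
    max_gap = max_gap if max_gap is not None else dg
    tests = window_enrichment(chip, control, window, step)
    tests["q_value"] = bh_fdr(tests["p_value"].to_numpy())
    sig = tests[tests["q_value"] < fdr]
    return merge_windows(sig, max_gap, mark=mark)


def peak_width_stats(domains: pd.DataFrame, width_range=(500, 1000), n_bins: int = 20) -> dict:
    """Width summary: median, fraction of widths inside ``width_range``
    (inclusive), and a histogram. Empty input gives NaN summaries, n=0."""
    if len(domains) == 0:
        return {"n": 0, "median_width": float("nan"),
                "fraction_in_range": float("nan"),
                "width_range": tuple(width_range),
                "histogram": (np.array([]), np.array([]))}
    widths = (domains["end"] - domains["start"]).to_numpy()
    lo, hi = width_range
    counts, edges = np.histogram(widths, bins=n_bins)
    return {
        "n": int(len(widths)),
        "median_width": float(np.median(widths)),
        "fraction_in_range": float(np.mean((widths >= lo) & (widths <= hi))),
        "width_range": (lo, hi),
        "histogram": (counts, edges),
    }


def classify_domain_context(domains: pd.DataFrame, partition: GenomePartition) -> pd.DataFrame:
    """Label each domain tss_proximal / genic / intergenic.

    A domain with any overlap of a TSS window or gene body takes the larger
    of those two overlaps (ties favour tss_proximal); it is intergenic only
    when it overlaps neither. Returns a copy with a ``context`` column.
    """
    out = domains.copy()
    context = np.empty(len(out), dtype=object)
    idx = np.arange(len(out))
    chrom_arr = out["chrom"].to_numpy() if len(out) else np.array([])
    for chrom in pd.unique(chrom_arr):
        sel = idx[chrom_arr == chrom]
        s = out["start"].to_numpy()[sel]
        e = out["end"].to_numpy()[sel]
        tss_set, genic_set, _ = partition.context_sets(chrom)
        ov_tss = iv.overlap_lengths(tss_set, s, e)
        ov_gen = iv.overlap_lengths(genic_set, s, e)
        lab = np.where(
            (ov_tss == 0) & (ov_gen == 0), "intergenic",
            np.where(ov_tss >= ov_gen, "tss_proximal", "genic"),
        )
        context[sel] = lab
    out["context"] = context
    return out


def context_fractions(domains: pd.DataFrame) -> pd.Series:
    """Share of domains per genomic context."""
    if len(domains) == 0:
        return pd.Series(0.0, index=list(GenomePartition.CONTEXTS))
    frac = domains["context"].value_counts(normalize=True)
    return frac.reindex(GenomePartition.CONTEXTS, fill_value=0.0)


def write_domains_bed(domains: pd.DataFrame, path) -> None:
    """BED6+: name = mark, score = int(10 x -log10 q)."""
    with open(path, "w") as fh:
        for row in domains.itertuples(index=False):
            score = int(round(10 * row.score))
            extra = f"\t{row.context}" if hasattr(row, "context") else ""
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.mark}\t{score}\t.{extra}\n")


@dataclass
class WindowTest:
    """One sliding-window enrichment test (row view of window_enrichment)."""

    chrom: str
    start: int
    end: int
    k_chip: int
    lambda_bg: float
    p_value: float
    q_value: float | None = None
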