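"""Gene models, canonical TSSs, and the TSS-proximal / genic / intergenic
partition of the genome.

Coordinates are 0-based half-open throughout (BED convention). The canonical
TSS of a gene is the 5'-most transcript start on the gene's strand: the
minimum start for ``+`` genes, the maximum 5' position for ``-`` genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import intervals as iv

DEFAULT_TSS_FLANK = 2000
"""Half-width (bp) of the TSS-proximal window used for partitioning and
state calling. Chosen to keep bivalent calls local to the TSS; the metagene
plots use a wider +/-3 kb view but that is a display window, not a call
window."""


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and lengths."""

    lengths: dict[str, int]

    def __post_init__(self):
        if not self.lengths:
            raise ValueError("layout must contain at least one chromosome")
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")

    @property
    def chroms(self) -> list[str]:
        return list(self.lengths)

    @property
    def genome_length(self) -> int:
        return sum(self.lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths


def read_chrom_sizes(path) -> GenomeLayout:
    """Read a two-column ``chrom<TAB>length`` file."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
            name = parts[0]
            if name in lengths:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            lengths[name] = int(parts[1])
    return GenomeLayout(lengths)


@dataclass
class GeneModel:
    """One gene, possibly aggregated from several transcript records.

    ``transcript_starts`` holds the 5' position of each transcript on the
    gene's strand (BED start for ``+``, ``end - 1`` for ``-``).
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    transcript_starts: set[int] = field(default_factory=set)
    flags: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: invalid strand {self.strand!r}")
        if not (0 <= self.tx_start < self.tx_end):
            raise ValueError(f"gene {self.gene_id!r}: invalid extent")
        if not self.transcript_starts:
            self.transcript_starts = {
                self.tx_start if self.strand == "+" else self.tx_end - 1
            }


def load_gene_models(path, layout: GenomeLayout) -> list[GeneModel]:
    """Read gene models from a BED file (>=6 columns; BED12 accepted, the
    block fields are ignored). Records sharing a name aggregate into one
    gene; their strand and chromosome must agree.
    """
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: need >=6 BED fields, got {len(parts)}")
            chrom, start, end, name, _score, strand = parts[:6]
            try:
                start, end = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if chrom not in layout:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            if not (0 <= start < end <= layout.lengths[chrom]):
                raise ValueError(f"{path}:{lineno}: coordinates out of bounds for {chrom}")
            five_prime = start if strand == "+" else end - 1
            if name in genes:
                g = genes[name]
                if g.chrom != chrom or g.strand != strand:
                    raise ValueError(
                        f"{path}:{lineno}: gene {name!r} has inconsistent chrom/strand"
                    )
                g.tx_start = min(g.tx_start, start)
                g.tx_end = max(g.tx_end, end)
                g.transcript_starts.add(five_prime)
            else:
                genes[name] = GeneModel(
                    gene_id=name, chrom=chrom, strand=strand,
                    tx_start=start, tx_end=end, transcript_starts={five_prime},
                )
    return list(genes.values())


def canonical_tss(genes: list[GeneModel]) -> pd.DataFrame:
    """One TSS per gene: min transcript 5' position for ``+`` genes, max for
    ``-`` genes. Returns a DataFrame indexed by gene_id with columns
    chrom, strand, tss.
    """
    if not genes:
        raise ValueError("gene list is empty")
    rows = {}
    for g in genes:
        tss = min(g.transcript_starts) if g.strand == "+" else max(g.transcript_starts)
        rows[g.gene_id] = (g.chrom, g.strand, int(tss))
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["chrom", "strand", "tss"])
    df.index.name = "gene_id"
    return df


@dataclass
class GenomePartition:
    """Disjoint-by-priority interval sets covering the genome.

    Priority: tss_proximal > genic > intergenic. Each field maps chromosome
    name to a merged ``(starts, ends)`` pair.
    """

    layout: GenomeLayout
    tss_proximal: dict[str, iv.IntervalArray]
    genic: dict[str, iv.IntervalArray]
    intergenic: dict[str, iv.IntervalArray]
    flank: int

    CONTEXTS = ("tss_proximal", "genic", "intergenic")

    def context_sets(self, chrom: str):
        return (
            self.tss_proximal.get(chrom, iv.empty()),
            self.genic.get(chrom, iv.empty()),
            self.intergenic.get(chrom, iv.empty()),
        )


def partition_genome(
    genes: list[GeneModel], layout: GenomeLayout, flank: int = DEFAULT_TSS_FLANK
) -> GenomePartition:
    """Partition each chromosome into TSS-proximal windows (TSS +/- flank),
    gene bodies outside those windows, and the intergenic remainder."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    tss_df = canonical_tss(genes) if genes else None
    tss_prox: dict[str, iv.IntervalArray] = {}
    genic: dict[str, iv.IntervalArray] = {}
    intergenic: dict[str, iv.IntervalArray] = {}
    bodies: dict[str, list[tuple[int, int]]] = {}
    windows: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        bodies.setdefault(g.chrom, []).append((g.tx_start, g.tx_end))
    if tss_df is not None:
        for chrom, sub in tss_df.groupby("chrom", sort=False):
            windows[chrom] = [
                (t - flank, t + flank) for t in sub["tss"].to_numpy()
            ]
    for chrom, length in layout.lengths.items():
        win = windows.get(chrom, [])
        if win:
            w = iv.clip(iv.merge(*zip(*win)), 0, length)
        else:
            w = iv.empty()
        bod = bodies.get(chrom, [])
        if bod:
            b = iv.clip(iv.merge(*zip(*bod)), 0, length)
        else:
            b = iv.empty()
        tss_prox[chrom] = w
        genic[chrom] = iv.subtract(b, w, length)
        covered = iv.merge(
            np.concatenate([w[0], b[0]]), np.concatenate([w[1], b[1]])
        ) if (w[0].size or b[0].size) else iv.empty()
        intergenic[chrom] = iv.complement(covered, length)
    return GenomePartition(layout, tss_prox, genic, intergenic, flank)
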