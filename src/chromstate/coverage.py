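"""Tag tracks, extended-fragment binned coverage, TSS-window intensities and
strand-oriented metagene profiles.

A *tag* is one aligned read, reduced to its 5' position and strand. Coverage
is computed after extending each tag to the nominal fragment length (default
200 bp) in its 3' direction, the standard single-end ChIP-seq treatment.
Normalized intensities are expressed per 10 million library tags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeLayout

NORMALIZATION_UNIT = 10_000_000  # tags-per-10-million
DEFAULT_EXTENSION = 200
DEFAULT_BIN_WIDTH = 50


@dataclass
class TagTrack:
    """Per-chromosome sorted 5' positions and strands of a tag library.

    ``chroms`` maps chromosome -> (positions int64 sorted, strands int8 with
    +1 for '+' and -1 for '-', co-sorted with positions).
    """

    layout: GenomeLayout
    chroms: dict[str, tuple[np.ndarray, np.ndarray]]
    library_size: int

    def positions(self, chrom: str) -> np.ndarray:
        return self.chroms.get(chrom, (np.empty(0, dtype=np.int64), None))[0]

    @classmethod
    def from_arrays(cls, layout, chrom_positions: dict[str, tuple[np.ndarray, np.ndarray]]):
        out = {}
        n = 0
        for chrom, (pos, strand) in chrom_positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            strand = np.asarray(strand, dtype=np.int8)
            order = np.argsort(pos, kind="stable")
            out[chrom] = (pos[order], strand[order])
            n += pos.size
        return cls(layout=layout, chroms=out, library_size=n)


def load_tags(path, layout: GenomeLayout, dedup: bool = True) -> TagTrack:
    """Load a BED6 tag file. The 5' position is ``start`` for '+' records and
    ``end - 1`` for '-' records. With ``dedup``, identical
    (chrom, 5' position, strand) tags collapse to one.
    """
    per_chrom: dict[str, tuple[list[int], list[int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 required (strand missing)")
            chrom, start, end, _name, _score, strand = parts[:6]
            start, end = int(start), int(end)
            if strand == "+":
                pos, sgn = start, 1
            elif strand == "-":
                pos, sgn = end - 1, -1
            else:
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            if chrom not in layout:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if not (0 <= pos < layout.lengths[chrom]):
                raise ValueError(
                    f"{path}:{lineno}: 5' position {pos} out of bounds on {chrom}"
                )
            bucket = per_chrom.setdefault(chrom, ([], []))
            bucket[0].append(pos)
            bucket[1].append(sgn)
    chroms = {}
    n = 0
    for chrom, (pos_list, sgn_list) in per_chrom.items():
        pos = np.array(pos_list, dtype=np.int64)
        sgn = np.array(sgn_list, dtype=np.int8)
        order = np.lexsort((sgn, pos))
        pos, sgn = pos[order], sgn[order]
        if dedup and pos.size:
            keep = np.concatenate(([True], (np.diff(pos) != 0) | (np.diff(sgn) != 0)))
            pos, sgn = pos[keep], sgn[keep]
        chroms[chrom] = (pos, sgn)
        n += pos.size
    return TagTrack(layout=layout, chroms=chroms, library_size=n)


def _fragment_bounds(pos: np.ndarray, sgn: np.ndarray, extension: int):
    """Half-open extended-fragment intervals per tag (unclipped)."""
    fs = np.where(sgn > 0, pos, pos - extension + 1)
    fe = fs + extension
    return fs, fe


@dataclass
class CoverageTrack:
    """Binned extended-fragment counts. A bin counts every fragment that
    overlaps it (not base-pair weighted)."""

    layout: GenomeLayout
    bin_width: int
    counts: dict[str, np.ndarray]
    library_size: int

    @property
    def normalization_factor(self) -> float:
        return NORMALIZATION_UNIT / self.library_size if self.library_size else float("nan")

    def total(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))


def extend_and_bin(
    track: TagTrack,
    bin_width: int = DEFAULT_BIN_WIDTH,
    extension: int = DEFAULT_EXTENSION,
) -> CoverageTrack:
    """Bin extended fragments: each tag increments every bin overlapped by
    its fragment [5'pos, 5'pos + extension) oriented along the strand,
    clipped to chromosome bounds."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if extension < 1:
        raise ValueError("extension must be >= 1")
    counts = {}
    for chrom, length in track.layout.lengths.items():
        n_bins = -(-length // bin_width)
        arr = np.zeros(n_bins + 1, dtype=np.int64)  # +1 slot for diff trick
        if chrom in track.chroms:
            pos, sgn = track.chroms[chrom]
            fs, fe = _fragment_bounds(pos, sgn, extension)
            fs = np.clip(fs, 0, length)
            fe = np.clip(fe, 0, length)
            valid = fe > fs
            b0 = fs[valid] // bin_width
            b1 = (fe[valid] - 1) // bin_width
            np.add.at(arr, b0, 1)
            np.add.at(arr, b1 + 1, -1)
            arr = np.cumsum(arr)
        counts[chrom] = arr[:n_bins]
    return CoverageTrack(track.layout, bin_width, counts, track.library_size)


def _window_counts(track: TagTrack, chrom: str, ws: np.ndarray, we: np.ndarray,
                   extension: int) -> np.ndarray:
    """Number of extended fragments overlapping each window [ws, we)."""
    out = np.zeros(len(ws), dtype=np.int64)
    if chrom not in track.chroms:
        return out
    pos, sgn = track.chroms[chrom]
    for sign in (1, -1):
        p = pos[sgn == sign]
        if p.size == 0:
            continue
        if sign > 0:
            # fragment [p, p+ext) overlaps [ws,we) iff ws-ext < p < we
            lo = np.searchsorted(p, ws - extension + 1, side="left")
            hi = np.searchsorted(p, we, side="left")
        else:
            # fragment [p-ext+1, p+1) overlaps iff ws <= p < we+ext-1
            lo = np.searchsorted(p, ws, side="left")
            hi = np.searchsorted(p, we + extension - 1, side="left")
        out += hi - lo
    return out


def tss_window_intensity(
    track: TagTrack,
    tss_table: pd.DataFrame,
    flank: int,
    extension: int = DEFAULT_EXTENSION,
    reference_library_size: int | None = None,
) -> pd.Series:
    """Normalized tag intensity per gene in [tss - flank, tss + flank).

    Intensity = extended-fragment overlap count x 1e7 / library size. By
    default the track's own library size is used; ``reference_library_size``
    substitutes another library (e.g. the matched input) as the scaling
    denominator for cross-sample comparisons.
    """
    lib = reference_library_size if reference_library_size is not None else track.library_size
    if lib <= 0:
        raise ValueError("cannot normalize: library size is 0")
    values = np.zeros(len(tss_table), dtype=float)
    idx = np.arange(len(tss_table))
    for chrom, sub in tss_table.groupby("chrom", sort=False):
        t = sub["tss"].to_numpy(dtype=np.int64)
        counts = _window_counts(track, chrom, t - flank, t + flank, extension)
        values[idx[tss_table["chrom"].to_numpy() == chrom]] = counts
    return pd.Series(values * (NORMALIZATION_UNIT / lib), index=tss_table.index,
                     name="intensity")


@dataclass
class MetageneProfile:
    """Mean normalized intensity by offset from the TSS, strand-oriented
    (negative offsets are upstream in the gene's orientation)."""

    offsets: np.ndarray          # bin start offsets, bp
    values: np.ndarray           # mean normalized intensity per bin
    bin_width: int
    n_genes: int

    def peak_offset(self) -> int:
        """Offset (bin start, bp) of the maximum of the profile."""
        return int(self.offsets[int(np.argmax(self.values))])


def metagene_profile(
    track: TagTrack,
    tss_table: pd.DataFrame,
    flank: int = 3000,
    bin_width: int = DEFAULT_BIN_WIDTH,
    extension: int = DEFAULT_EXTENSION,
) -> MetageneProfile:
    """Average extended-fragment counts in bins covering TSS +/- flank,
    oriented 5'->3' along each gene, normalized per 10M tags and per gene."""
    if len(tss_table) == 0:
        raise ValueError("need at least one gene")
    if track.library_size <= 0:
        raise ValueError("cannot normalize: empty library")
    if flank % bin_width:
        raise ValueError("flank must be a multiple of bin_width")
    n_bins = 2 * flank // bin_width
    offsets = np.arange(-flank, flank, bin_width)
    acc = np.zeros(n_bins, dtype=float)
    for chrom, sub in tss_table.groupby("chrom", sort=False):
        for strand, ssub in sub.groupby("strand", sort=False):
            t = ssub["tss"].to_numpy(dtype=np.int64)
            # bin at gene offset o covers the bin_width bases starting o
            # bases 5'->3' of the TSS; for '-' genes that is
            # [tss - o - bin_width + 1, tss - o + 1) in genome coordinates.
            if strand == "+":
                ws = (t[:, None] + offsets[None, :]).ravel()
            else:
                ws = (t[:, None] - offsets[None, :] - bin_width + 1).ravel()
            counts = _window_counts(track, chrom, ws, ws + bin_width, extension)
            acc += counts.reshape(len(t), n_bins).sum(axis=0)
    values = acc * (NORMALIZATION_UNIT / track.library_size) / len(tss_table)
    return MetageneProfile(offsets=offsets, values=values, bin_width=bin_width,
                           n_genes=len(tss_table))


def write_bedgraph(cov: CoverageTrack, path, normalized: bool = False) -> None:
    """Write non-zero bins as bedGraph."""
    factor = cov.normalization_factor if normalized else 1
    with open(path, "w") as fh:
        for chrom, arr in cov.counts.items():
            nz = np.flatnonzero(arr)
            length = cov.layout.lengths[chrom]
            for i in nz:
                start = i * cov.bin_width
                end = min(start + cov.bin_width, length)
                fh.write(f"{chrom}\t{start}\t{end}\t{arr[i] * factor}\n")


def write_profile_tsv(profile: MetageneProfile, path) -> None:
    pd.DataFrame({"offset": profile.offsets, "intensity": profile.values}).to_csv(
        path, sep="\t", index=False
    )
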