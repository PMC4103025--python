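"""Four-state TSS chromatin classification and cross-condition comparison.

Each gene's TSS window is tested for overlap with called H3K4me3 and
H3K27me3 domains; the pair of flags maps deterministically onto one of four
states: K4_ONLY, K27_ONLY, BIVALENT (both marks) or NONE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import DEFAULT_TSS_FLANK

STATES = ("K4_ONLY", "K27_ONLY", "BIVALENT", "NONE")

#: single-letter codes used by locus mosaic strings
STATE_LETTERS = {"K4_ONLY": "K", "BIVALENT": "B", "K27_ONLY": "R", "NONE": "N"}


def mark_presence(
    domains_by_mark: dict[str, pd.DataFrame],
    tss_table: pd.DataFrame,
    flank: int = DEFAULT_TSS_FLANK,
) -> pd.DataFrame:
    """Boolean gene x mark table: True iff any domain of the mark overlaps
    the half-open window [tss - flank, tss + flank)."""
    out = pd.DataFrame(index=tss_table.index)
    chroms = tss_table["chrom"].to_numpy()
    tss = tss_table["tss"].to_numpy(dtype=np.int64)
    for mark, domains in domains_by_mark.items():
        flag = np.zeros(len(tss_table), dtype=bool)
        for chrom in pd.unique(chroms):
            sel = chroms == chrom
            if len(domains):
                sub = domains[domains["chrom"] == chrom].sort_values("start")
                ds = sub["start"].to_numpy(dtype=np.int64)
                de = sub["end"].to_numpy(dtype=np.int64)
            else:
                ds = de = np.empty(0, dtype=np.int64)
            if ds.size == 0:
                continue
            ws, we = tss[sel] - flank, tss[sel] + flank
            # domain overlaps window iff some domain start < we and end > ws;
            # domains may overlap each other, so test against running max end
            run_end = np.maximum.accumulate(de)
            i = np.searchsorted(ds, we, side="left") - 1
            hit = np.zeros(ws.shape, dtype=bool)
            ok = i >= 0
            hit[ok] = run_end[i[ok]] > ws[ok]
            flag[sel] = hit
        out[mark] = flag
    return out


def classify_states(
    flags: pd.DataFrame, k4_col: str = "H3K4me3", k27_col: str = "H3K27me3",
    condition: str | None = None,
) -> pd.DataFrame:
    """Map (has_k4, has_k27) flags to the four-state label.

    Returns a DataFrame indexed by gene with columns has_k4, has_k27, state
    (and condition when given).
    """
    for col in (k4_col, k27_col):
        if col not in flags.columns:
            raise ValueError(f"missing mark flags column {col!r}")
    k4 = flags[k4_col].to_numpy(dtype=bool)
    k27 = flags[k27_col].to_numpy(dtype=bool)
    state = np.where(
        k4 & k27, "BIVALENT",
        np.where(k4, "K4_ONLY", np.where(k27, "K27_ONLY", "NONE")),
    )
    out = pd.DataFrame({"has_k4": k4, "has_k27": k27, "state": state},
                       index=flags.index)
    out.index.name = "gene_id"
    if condition is not None:
        out["condition"] = condition
    return out


def state_counts(calls: pd.DataFrame) -> pd.DataFrame:
    """Counts and proportions per state (all four states always present)."""
    counts = calls["state"].value_counts().reindex(STATES, fill_value=0)
    n = int(counts.sum())
    props = counts / n if n else counts.astype(float)
    return pd.DataFrame({"count": counts, "proportion": props})


@dataclass
class StateTransitionTable:
    """4x4 state transition counts between two conditions."""

    table: pd.DataFrame            # rows: condition A state, cols: condition B
    retention: pd.Series           # diagonal / row sum per state
    n_shared: int
    only_in_a: list[str]
    only_in_b: list[str]


def transition_table(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> StateTransitionTable:
    """Cross-tabulate per-gene states between two conditions over their
    shared genes. Genes absent from either condition are reported
    separately, not counted."""
    shared = calls_a.index.intersection(calls_b.index)
    if len(shared) == 0:
        raise ValueError("conditions share no genes")
    a = calls_a.loc[shared, "state"]
    b = calls_b.loc[shared, "state"]
    table = pd.crosstab(a, b).reindex(index=STATES, columns=STATES, fill_value=0)
    table.index.name = "from"
    table.columns.name = "to"
    rowsum = table.sum(axis=1)
    diag = pd.Series(np.diag(table), index=table.index)
    retention = diag / rowsum.replace(0, np.nan)
    return StateTransitionTable(
        table=table,
        retention=retention,
        n_shared=int(len(shared)),
        only_in_a=sorted(calls_a.index.difference(calls_b.index)),
        only_in_b=sorted(calls_b.index.difference(calls_a.index)),
    )


def compare_gene_sets(set_a, set_b, universe) -> dict:
    """Two-set overlap report relative to each set and to the universe."""
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u or not b <= u:
        raise ValueError("both sets must be subsets of the universe")
    inter = a & b
    report = {
        "n_a": len(a), "n_b": len(b), "n_universe": len(u),
        "intersection": len(inter),
        "a_only": len(a - b), "b_only": len(b - a),
        "share_of_a": len(inter) / len(a) if a else float("nan"),
        "share_of_b": len(inter) / len(b) if b else float("nan"),
        "share_of_universe": len(inter) / len(u) if u else float("nan"),
    }
    return report


def write_state_calls(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t")


def write_transition_table(tt: StateTransitionTable, path) -> None:
    tt.table.to_csv(path, sep="\t")
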