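"""Expression integration: state-vs-expression comparison, condition
signatures, fold-change screens and hypergeometric gene-set enrichment.

Expression values are log2 intensities (microarray-style); fold changes are
interpreted on the linear scale, so a ">40% reduction" means
``2**(old - young) < 0.6``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .domains import bh_fdr
from .states import STATES


def read_expression_tsv(path) -> pd.DataFrame:
    """Gene x condition log2-intensity table; first column = gene_id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValueError(f"{path}: expression table contains non-finite values")
    return df


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene sets: name<TAB>description<TAB>gene1<TAB>gene2..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >=3 fields")
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def expression_by_state(expr: pd.DataFrame, calls: pd.DataFrame, condition: str) -> dict:
    """Per-state expression summaries plus a two-sided Wilcoxon rank-sum test
    of bivalent genes against all genes.

    Returns {"summary": DataFrame(n, median, q1, q3 per state),
    "bivalent_vs_all_p": float (NaN when either group is empty)}.
    """
    if condition not in expr.columns:
        raise ValueError(f"unknown condition {condition!r}")
    shared = expr.index.intersection(calls.index)
    values = expr.loc[shared, condition]
    state = calls.loc[shared, "state"]
    rows = []
    for s in STATES:
        v = values[state == s]
        if len(v):
            rows.append((s, len(v), float(v.median()),
                         float(v.quantile(0.25)), float(v.quantile(0.75))))
        else:
            rows.append((s, 0, float("nan"), float("nan"), float("nan")))
    summary = pd.DataFrame(rows, columns=["state", "n", "median", "q1", "q3"]).set_index("state")
    biv = values[state == "BIVALENT"]
    if len(biv) and len(values):
        p = float(stats.ranksums(biv, values).pvalue)
    else:
        p = float("nan")
    return {"summary": summary, "bivalent_vs_all_p": p}


def condition_signature(
    expr: pd.DataFrame,
    target: str,
    others: list[str],
    min_score: float = 1.0,
    min_level: float = 6.0,
) -> pd.DataFrame:
    """Genes specific to ``target``: specificity score = target log2 level
    minus the best level in any other condition; a gene qualifies when the
    score >= min_score (default 1, i.e. 2-fold) and its target-condition
    level >= min_level (detection threshold)."""
    if target in others:
        raise ValueError("target condition cannot be among the others")
    for cond in [target, *others]:
        if cond not in expr.columns:
            raise ValueError(f"unknown condition {cond!r}")
    score = expr[target] - expr[list(others)].max(axis=1)
    keep = (score >= min_score) & (expr[target] >= min_level)
    out = pd.DataFrame({
        "specificity_score": score[keep],
        "level": expr.loc[keep, target],
    }).sort_values("specificity_score", ascending=False)
    out.attrs.update(condition=target, min_score=min_score, min_level=min_level)
    return out


def fold_change_report(
    expr: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    reduction_threshold: float = 0.4,
    family_flags: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Linear-scale reduction screen from ``cond_a`` (e.g. young) to
    ``cond_b`` (e.g. old): a gene is flagged when 2**(b - a), the linear
    ratio, falls below 1 - reduction_threshold.

    ``family_flags`` (gene_id -> family label, e.g. histone subfamilies)
    adds a family column; rollup counts live in ``.attrs['family_counts']``.
    """
    for cond in (cond_a, cond_b):
        if cond not in expr.columns:
            raise ValueError(f"unknown condition {cond!r}")
    ratio = np.power(2.0, expr[cond_b] - expr[cond_a])
    out = pd.DataFrame({
        cond_a: expr[cond_a], cond_b: expr[cond_b],
        "linear_ratio": ratio,
        "flagged": ratio < (1.0 - reduction_threshold),
    })
    if family_flags is not None:
        out["family"] = pd.Series(family_flags).reindex(out.index)
        counts = (
            out.loc[out["flagged"] & out["family"].notna(), "family"]
            .value_counts().to_dict()
        )
        out.attrs["family_counts"] = counts
    out.attrs["reduction_threshold"] = reduction_threshold
    return out


def gene_set_enrichment(
    gene_list,
    universe,
    annotations: dict[str, set[str]],
    min_set_size: int = 3,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``gene_list`` in each
    annotation set, BH-corrected across sets.

    p = P(X >= k) for X ~ Hypergeom(N=|universe|, K=|set|, n=|list|), with
    sets intersected with the universe first.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    genes = set(gene_list)
    if not genes <= universe:
        raise ValueError("gene list must be a subset of the universe")
    N, n = len(universe), len(genes)
    rows = []
    for name, members in annotations.items():
        members = members & universe
        K = len(members)
        if K < min_set_size:
            continue
        k = len(members & genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, p))
    df = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p_value"]).set_index("set")
    if len(df):
        df["q_value"] = bh_fdr(df["p_value"].to_numpy())
        df = df.sort_values("p_value")
    else:
        df["q_value"] = pd.Series(dtype=float)
    return df
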