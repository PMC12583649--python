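"""Differential influence (DIR) and differential expression (DEG) analysis.

Per feature, a two-sided Welch t-test contrasts condition B against
condition A; p-values are Benjamini-Hochberg adjusted across features.
Classification uses the strict inequalities

* DIR: ``up`` iff adj_p < 0.05 and delta influence > 0.5 (``down`` mirrored);
* DEG: ``up`` iff adj_p < 0.05 and fold change > 1.5 on log2-scale values
  (|log2 FC| > log2 1.5 ~= 0.585).

Over-representation of gene sets in a DEG list uses the hypergeometric
upper tail, BH-adjusted across sets in batch mode, with gene ratios
(overlap / query size) reported.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CoregflowError, ExpressionDataset
from .influence import InfluenceMatrix

__all__ = [
    "welch_two_sample",
    "bh_adjust",
    "identify_dirs",
    "identify_degs",
    "hypergeom_enrichment",
    "enrich_gene_sets",
    "read_gmt",
]

RESULT_COLUMNS = [
    "feature_id",
    "mean_A",
    "mean_B",
    "delta",
    "log2_fc",
    "t_value",
    "p_value",
    "adj_p",
    "class",
]


def welch_two_sample(values_a, values_b) -> tuple[float, float, float]:
    """Welch's two-sided t-test of B against A.

    Returns (t, p, delta) with ``delta = mean(B) - mean(A)``; the t
    statistic carries delta's sign (Welch-Satterthwaite degrees of
    freedom).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise CoregflowError("each group needs >= 2 values")
    t, p = stats.ttest_ind(b, a, equal_var=False)
    return float(t), float(p), float(b.mean() - a.mean())


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise CoregflowError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _condition_groups(
    condition_of: Mapping[str, str], samples: list[str], condition_a: str, condition_b: str
) -> tuple[list[str], list[str]]:
    ga = [s for s in samples if condition_of[s] == condition_a]
    gb = [s for s in samples if condition_of[s] == condition_b]
    for name, g in ((condition_a, ga), (condition_b, gb)):
        if len(g) < 2:
            raise CoregflowError(f"condition {name!r} has fewer than 2 samples")
    return ga, gb


def _welch_table(
    matrix: pd.DataFrame,
    cols_a: list[str],
    cols_b: list[str],
) -> pd.DataFrame:
    A = matrix[cols_a].to_numpy(dtype=float)
    B = matrix[cols_b].to_numpy(dtype=float)
    t, p = stats.ttest_ind(B, A, axis=1, equal_var=False)
    mean_a = A.mean(axis=1)
    mean_b = B.mean(axis=1)
    return pd.DataFrame(
        {
            "feature_id": matrix.index,
            "mean_A": mean_a,
            "mean_B": mean_b,
            "delta": mean_b - mean_a,
            "t_value": t,
            "p_value": p,
        }
    )


def identify_dirs(
    influence: InfluenceMatrix,
    condition_of: Mapping[str, str],
    condition_a: str,
    condition_b: str,
    adj_p_max: float = 0.05,
    min_abs_delta: float = 0.5,
) -> pd.DataFrame:
    """Differentially influential regulators, condition B vs condition A.

    One row per eligible regulator: condition means of influence, raw mean
    difference ``delta``, Welch t/p, BH-adjusted p across regulators, and
    class ``up`` (adj_p < threshold and delta > min_abs_delta, strictly),
    ``down`` (mirrored) or ``ns``.
    """
    eligible = influence.eligible_regulators()
    if not eligible:
        raise CoregflowError("no eligible regulators in influence matrix")
    # regulators with undefined scores in any sample (zero-variance regulon
    # in that sample) cannot be tested
    mat = influence.values.loc[eligible].dropna(axis=0, how="any")
    if mat.empty:
        raise CoregflowError("no regulator has complete influence values")
    ga, gb = _condition_groups(condition_of, list(mat.columns), condition_a, condition_b)
    out = _welch_table(mat, ga, gb)
    out["log2_fc"] = np.nan
    out["adj_p"] = bh_adjust(out["p_value"])
    cls = np.where(
        (out["adj_p"] < adj_p_max) & (out["delta"] > min_abs_delta),
        "up",
        np.where(
            (out["adj_p"] < adj_p_max) & (out["delta"] < -min_abs_delta), "down", "ns"
        ),
    )
    out["class"] = cls
    return out[RESULT_COLUMNS].reset_index(drop=True)


def identify_degs(
    expr: ExpressionDataset,
    condition_a: str,
    condition_b: str,
    adj_p_max: float = 0.05,
    min_fold_change: float = 1.5,
) -> pd.DataFrame:
    """Differentially expressed genes on log2-scale values, B vs A.

    ``log2_fc = mean_B - mean_A``; class ``up`` iff adj_p < threshold and
    fold change > ``min_fold_change`` (strict), ``down`` mirrored.
    """
    if expr.condition_of is None:
        raise CoregflowError("expression dataset has no condition design")
    ga, gb = _condition_groups(
        expr.condition_of, expr.sample_ids, condition_a, condition_b
    )
    out = _welch_table(expr.values, ga, gb)
    out["log2_fc"] = out["delta"]
    out["adj_p"] = bh_adjust(out["p_value"])
    lfc_min = math.log2(min_fold_change)
    cls = np.where(
        (out["adj_p"] < adj_p_max) & (out["log2_fc"] > lfc_min),
        "up",
        np.where(
            (out["adj_p"] < adj_p_max) & (out["log2_fc"] < -lfc_min), "down", "ns"
        ),
    )
    out["class"] = cls
    return out[RESULT_COLUMNS].reset_index(drop=True)


def hypergeom_enrichment(
    query_genes: set[str], gene_set: set[str], universe: set[str]
) -> tuple[int, float]:
    """Upper-tail hypergeometric over-representation of ``gene_set``.

    Returns (overlap, P(X >= overlap)) for drawing |query| genes from the
    universe with |gene_set| marked.
    """
    if not universe:
        raise CoregflowError("empty universe")
    if not query_genes:
        raise CoregflowError("empty query gene list")
    if not (query_genes <= universe and gene_set <= universe):
        raise CoregflowError("query and gene_set must be subsets of the universe")
    overlap = len(query_genes & gene_set)
    p = float(
        stats.hypergeom.sf(overlap - 1, len(universe), len(gene_set), len(query_genes))
    )
    return overlap, min(p, 1.0)


def enrich_gene_sets(
    query_genes: set[str],
    collections: Mapping[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Batch over-representation across a gene-set collection.

    One row per set: overlap, gene ratio (overlap / |query|), raw and
    BH-adjusted p (adjusted across the collection).
    """
    rows = []
    for name in sorted(collections):
        gene_set = collections[name] & universe
        overlap, p = hypergeom_enrichment(query_genes, gene_set, universe)
        rows.append(
            {
                "gene_set": name,
                "set_size": len(gene_set),
                "overlap": overlap,
                "gene_ratio": overlap / len(query_genes),
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["adj_p"] = bh_adjust(out["p_value"])
    else:
        out["adj_p"] = []
    return out


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection (name, description, genes...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets
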