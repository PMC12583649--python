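"""Per-sample regulator influence scores.

The influence of regulator ``r`` in one sample is a Welch-type contrast
between the expression of the genes it activates (A^r) and the genes it
represses (I^r) within that sample:

    influence(r) = (mean(E[A^r]) - mean(E[I^r]))
                   / sqrt(var(E[A^r]) / |A^r| + var(E[I^r]) / |I^r|)

with unbiased (n-1) variances.  A positive value means the activated
targets sit above the repressed ones, i.e. the regulator behaves as the
network model expects — it is "active".  Influence is only reported for
regulators with at least ``min_targets`` regulon genes (default 5).

Regulators with a one-sided regulon (no repressed or no activated targets)
leave the formula undefined; by default the nonempty side is contrasted
against all profiled genes outside the regulon (flagged
``one-sided-fallback``); ``one_sided="strict"`` excludes them instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CoregflowError, ExpressionDataset, RegulatoryNetwork

__all__ = [
    "InfluenceMatrix",
    "regulator_targets",
    "sample_influence",
    "influence_matrix",
    "activity_check",
]

logger = logging.getLogger(__name__)

ELIGIBLE = "eligible"
TOO_FEW = "too-few-targets"
ONE_SIDED = "one-sided-fallback"
UNDEFINED = "undefined"


@dataclass
class InfluenceMatrix:
    """Regulators x samples influence scores with per-regulator eligibility.

    ``values`` holds NaN rows for regulators without a score; ``flags``
    maps each regulator to eligible / too-few-targets / one-sided-fallback
    / undefined.
    """

    values: pd.DataFrame
    flags: dict[str, str]

    def eligible_regulators(self) -> list[str]:
        return [r for r in self.values.index if self.flags[r] in (ELIGIBLE, ONE_SIDED)]


def regulator_targets(
    network: RegulatoryNetwork, regulator: str
) -> tuple[set[str], set[str]]:
    """(A^r, I^r): the genes ``regulator`` activates and represses."""
    view = network.regulon_view()
    if regulator not in view:
        raise CoregflowError(f"regulator {regulator!r} not in any program")
    return view[regulator]


def _welch_contrast(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    num = a.mean() - b.mean()
    den = np.sqrt(a.var(ddof=1) / na + b.var(ddof=1) / nb)
    if den == 0:
        return float("nan")
    return float(num / den)


def sample_influence(expr_column: pd.Series, a_genes, i_genes) -> float:
    """Influence of one regulator in one sample.

    ``expr_column`` is the per-gene expression of that sample; ``a_genes``
    and ``i_genes`` are A^r and I^r.  Both sets must have >= 2 genes for
    the variances to exist; a zero denominator gives NaN.
    """
    a = expr_column.loc[sorted(a_genes)].to_numpy(dtype=float)
    b = expr_column.loc[sorted(i_genes)].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise CoregflowError("each regulon side needs >= 2 genes for a contrast")
    return _welch_contrast(a, b)


def influence_matrix(
    expr: ExpressionDataset,
    network: RegulatoryNetwork,
    min_targets: int = 5,
    min_targets_mode: str = "combined",
    one_sided: str = "fallback",
    standardize: bool = True,
) -> InfluenceMatrix:
    """Influence of every network regulator in every sample of ``expr``.

    The query matrix is per-gene standardized first (``standardize=False``
    uses raw values).  ``min_targets_mode`` is ``combined`` (|A|+|I| >=
    min_targets, the default reading of the eligibility rule) or
    ``per_side`` (each nonempty side alone must reach it).
    """
    if min_targets_mode not in ("combined", "per_side"):
        raise CoregflowError(f"unknown min_targets_mode {min_targets_mode!r}")
    if one_sided not in ("fallback", "strict"):
        raise CoregflowError(f"unknown one_sided policy {one_sided!r}")

    genes = set(expr.gene_ids)
    net_targets = network.targets
    overlap = genes & net_targets
    if not overlap:
        raise CoregflowError("query dataset shares no genes with network targets")
    logger.info(
        "query/network target overlap: %d/%d (%.1f%%)",
        len(overlap),
        len(net_targets),
        100 * len(overlap) / len(net_targets),
    )

    data = expr.standardized() if standardize else expr
    X = data.values.to_numpy(dtype=float)
    gene_pos = {g: i for i, g in enumerate(data.gene_ids)}
    view = network.regulon_view()
    regulators = sorted(view)
    samples = data.sample_ids

    values = np.full((len(regulators), len(samples)), np.nan)
    flags: dict[str, str] = {}
    for i, r in enumerate(regulators):
        a_all, i_all = view[r]
        a_set = sorted(a_all & genes)
        i_set = sorted(i_all & genes)
        if min_targets_mode == "combined":
            eligible = len(a_set) + len(i_set) >= min_targets
        else:
            sides = [s for s in (a_set, i_set) if s]
            eligible = bool(sides) and all(len(s) >= min_targets for s in sides)
        if not eligible:
            flags[r] = TOO_FEW
            continue
        # a side with a single gene has no unbiased variance: contrast it
        # via the one-sided fallback instead
        if len(a_set) == 1:
            a_set = []
        if len(i_set) == 1:
            i_set = []
        flag = ELIGIBLE
        if not a_set or not i_set:
            if one_sided == "strict":
                flags[r] = UNDEFINED
                continue
            flag = ONE_SIDED
            rest = sorted(genes - a_all - i_all - {r})
            if a_set:
                i_set = rest
            else:
                a_set = rest
            if len(a_set) < 2 or len(i_set) < 2:
                flags[r] = UNDEFINED
                continue
        ai = np.array([gene_pos[g] for g in a_set])
        ii = np.array([gene_pos[g] for g in i_set])
        xa, xi = X[ai], X[ii]
        num = xa.mean(axis=0) - xi.mean(axis=0)
        den = np.sqrt(
            xa.var(axis=0, ddof=1) / len(ai) + xi.var(axis=0, ddof=1) / len(ii)
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            row = num / den
        row[~np.isfinite(row)] = np.nan
        values[i] = row
        flags[r] = flag

    return InfluenceMatrix(
        pd.DataFrame(values, index=regulators, columns=samples), flags
    )


def activity_check(influence_value: float) -> bool:
    """A regulator is active only on a strictly positive influence value."""
    return bool(influence_value > 0)
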