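"""LICORN-style cooperative network inference.

The procedure works on a three-state discretization of the compendium:
per gene, values beyond ``z_threshold`` unbiased standard deviations from
the gene's mean become +1 / -1, the rest 0.  Candidate co-regulator sets are
mined with a level-wise (apriori) search for sets that are jointly +1 or
jointly -1 in at least ``min_support`` of the samples.  For every target
gene, activator/repressor set pairs (A, I) drawn from the mined candidates
(either side may be empty, not both) are scored by the mean absolute
difference between the predicted state ``sign(state(A) - state(I))`` and the
target's observed discrete state; the best-fitting programs are kept.

All orderings are deterministic: candidate sets by support descending then
lexicographic; program ties by fit, then total regulator count, then
lexicographic member order.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    CoregflowError,
    ExpressionDataset,
    LocalProgram,
    RegulatorCatalog,
    RegulatoryNetwork,
)

__all__ = [
    "DiscreteMatrix",
    "CandidateSet",
    "discretize",
    "collective_state",
    "predict_target",
    "score_program",
    "mine_candidates",
    "infer_candidate_programs",
    "infer_network",
    "edge_f1",
]


@dataclass
class DiscreteMatrix:
    """Genes x samples matrix with values in {-1, 0, +1}."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.isin(arr, (-1, 0, 1)).all():
            raise CoregflowError("discrete matrix may only contain -1, 0, +1")
        self.values = self.values.astype(np.int8)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class CandidateSet:
    """A co-regulator set with its joint-activity support."""

    members: frozenset[str]
    support: float

    def __post_init__(self) -> None:
        if not self.members:
            raise CoregflowError("candidate set must be non-empty")
        if not (0.0 <= self.support <= 1.0):
            raise CoregflowError("support outside [0, 1]")


def discretize(expr: ExpressionDataset, z_threshold: float = 1.0) -> DiscreteMatrix:
    """Three-state per-gene standardization of an expression matrix.

    Per gene: standardize across samples (mean, unbiased SD); +1 where the
    z-score is >= ``z_threshold``, -1 where <= ``-z_threshold``, else 0.
    Zero-variance genes map to all-0 rows.
    """
    if expr.n_samples < 2:
        raise CoregflowError("discretization needs at least 2 samples")
    x = expr.values.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    out = np.zeros_like(x, dtype=np.int8)
    ok = (sd > 0).ravel()
    z = np.zeros_like(x)
    z[ok] = (x[ok] - mu[ok]) / sd[ok]
    out[z >= z_threshold] = 1
    out[z <= -z_threshold] = -1
    return DiscreteMatrix(
        pd.DataFrame(out, index=expr.values.index, columns=expr.values.columns)
    )


def collective_state(members, disc: DiscreteMatrix, sample: str) -> int:
    """Collective discrete state of a regulator set in one sample.

    Sign of the member-state median; an even split (midpoint median 0)
    and the empty set both give 0.
    """
    members = sorted(members)
    if not members:
        return 0
    states = disc.values.loc[members, sample].to_numpy()
    return int(np.sign(np.median(states)))


def predict_target(s_a: int, s_i: int) -> int:
    """Predicted target state from collective activator/repressor states.

    ``sign(s_a - s_i)``: activators up and repressors down both push the
    target up; concordant sides cancel.
    """
    return int(np.sign(s_a - s_i))


def score_program(program: LocalProgram, disc: DiscreteMatrix) -> float:
    """Mean absolute error between predicted and observed target states.

    Range [0, 2]; 0 is a perfect discrete fit.
    """
    total = 0.0
    samples = disc.sample_ids
    obs = disc.values.loc[program.target, :].to_numpy()
    for j, s in enumerate(samples):
        pred = predict_target(
            collective_state(program.activators, disc, s),
            collective_state(program.repressors, disc, s),
        )
        total += abs(pred - int(obs[j]))
    return total / len(samples)


# ---------------------------------------------------------------------------
# Candidate mining (level-wise apriori on joint +1 / joint -1 activity)
# ---------------------------------------------------------------------------


def mine_candidates(
    disc: DiscreteMatrix,
    regulators: RegulatorCatalog,
    min_support: float = 0.1,
    max_set_size: int = 4,
) -> list[CandidateSet]:
    """Mine regulator sets jointly active in >= ``min_support`` of samples.

    A set's support is the fraction of samples in which all members are +1
    plus the fraction in which all are -1; the support is anti-monotone, so
    a level-wise apriori search is exact.  Result ordered by support
    descending, then lexicographically.
    """
    regs = sorted(set(regulators.regulator_ids) & set(disc.gene_ids))
    n = len(disc.sample_ids)
    plus = {r: disc.values.loc[r].to_numpy() == 1 for r in regs}
    minus = {r: disc.values.loc[r].to_numpy() == -1 for r in regs}

    results: list[CandidateSet] = []
    # frontier: sorted member tuple -> (joint_plus, joint_minus)
    frontier: dict[tuple[str, ...], tuple[np.ndarray, np.ndarray]] = {}
    for r in regs:
        supp = (plus[r].sum() + minus[r].sum()) / n
        if supp >= min_support:
            frontier[(r,)] = (plus[r], minus[r])
            results.append(CandidateSet(frozenset((r,)), float(supp)))

    size = 1
    while frontier and size < max_set_size:
        next_frontier: dict[tuple[str, ...], tuple[np.ndarray, np.ndarray]] = {}
        keys = sorted(frontier)
        for a, b in itertools.combinations(keys, 2):
            if a[:-1] != b[:-1]:  # apriori prefix join on sorted tuples
                continue
            cand = a + (b[-1],)
            # prune: every (size)-subset must itself be frequent
            if size >= 2 and any(
                cand[:i] + cand[i + 1 :] not in frontier for i in range(len(cand))
            ):
                continue
            jp = frontier[a][0] & plus[cand[-1]]
            jm = frontier[a][1] & minus[cand[-1]]
            supp = (jp.sum() + jm.sum()) / n
            if supp >= min_support:
                next_frontier[cand] = (jp, jm)
                results.append(CandidateSet(frozenset(cand), float(supp)))
        frontier = next_frontier
        size += 1

    results.sort(key=lambda c: (-c.support, tuple(sorted(c.members))))
    return results


# ---------------------------------------------------------------------------
# Program search
# ---------------------------------------------------------------------------


def _candidate_state_matrix(
    cands: list[frozenset[str]], disc: DiscreteMatrix
) -> np.ndarray:
    """Collective-state matrix, one row per candidate set (row 0 = empty)."""
    n = len(disc.sample_ids)
    S = np.zeros((len(cands) + 1, n), dtype=np.int8)
    vals = disc.values
    for i, members in enumerate(cands, start=1):
        sub = vals.loc[sorted(members)].to_numpy()
        S[i] = np.sign(np.median(sub, axis=0)).astype(np.int8)
    return S


def infer_candidate_programs(
    expr: ExpressionDataset,
    regulators: RegulatorCatalog,
    min_support: float = 0.1,
    max_set_size: int = 4,
    z_threshold: float = 0.6,
    max_programs_per_gene: int = 400,
    fit_cutoff: float = 1.0,
    allow_regulator_targets: bool = False,
    min_coexpression: float = 0.09,
    max_regulators_per_target: int = 6,
) -> dict[str, list[LocalProgram]]:
    """Rank candidate local programs per target gene by discrete fit.

    Returns, per target, up to ``max_programs_per_gene`` programs with
    ``fit_score <= fit_cutoff``, best first.  Genes for which no candidate
    meets the cutoff map to an empty list.

    To avoid overfitting the discrete fit on the huge space of candidate
    pairs, candidate sets are screened per target: a set may act as
    activators (repressors) of a target only if every member's discrete
    co-expression with the target — the mean product of their three-state
    values — exceeds ``min_coexpression`` (falls below its negative) and
    ranks within the target's ``max_regulators_per_target`` strongest
    regulators in that direction.
    """
    if expr.n_samples < 8:
        warnings.warn(
            f"only {expr.n_samples} samples; inference is recommended with >= 8",
            stacklevel=2,
        )
    regulators = regulators.restrict_to(expr)
    disc = discretize(expr, z_threshold=z_threshold)
    mined = mine_candidates(disc, regulators, min_support, max_set_size)
    cand_sets = [c.members for c in mined]
    n = len(disc.sample_ids)

    if allow_regulator_targets:
        target_genes = list(disc.gene_ids)
    else:
        target_genes = [g for g in disc.gene_ids if g not in regulators.regulator_ids]
    if not target_genes or not cand_sets:
        return {g: [] for g in target_genes}

    reg_list = sorted(regulators.regulator_ids)
    reg_pos = {r: i for i, r in enumerate(reg_list)}
    X = disc.values.loc[target_genes].to_numpy()  # (T, n)
    Dreg = disc.values.loc[reg_list].to_numpy().astype(np.float32)
    coexpr = (Dreg @ X.T.astype(np.float32)) / n  # (R, T)

    # per-target regulator shortlists: direction-consistent co-expression
    # above the threshold, within the m strongest per direction
    m = max_regulators_per_target
    n_reg = len(reg_list)
    act_member = coexpr > min_coexpression
    rep_member = coexpr < -min_coexpression
    if m < n_reg:
        order = np.argsort(-coexpr, axis=0, kind="stable")
        rank_pos = np.empty_like(order)
        np.put_along_axis(rank_pos, order, np.arange(n_reg)[:, None], axis=0)
        act_member &= rank_pos < m
        order = np.argsort(coexpr, axis=0, kind="stable")
        np.put_along_axis(rank_pos, order, np.arange(n_reg)[:, None], axis=0)
        rep_member &= rank_pos < m

    # collective states of mined sets, shared across targets
    S = _candidate_state_matrix(cand_sets, disc)  # row 0 = empty set
    set_masks = np.zeros((len(cand_sets) + 1, n_reg), dtype=bool)
    for i, members in enumerate(cand_sets, start=1):
        for r in members:
            set_masks[i, reg_pos[r]] = True
    sorted_members = [()] + [tuple(sorted(ms)) for ms in cand_sets]
    set_sizes = set_masks.sum(axis=1)

    out: dict[str, list[LocalProgram]] = {}
    for t_i, g in enumerate(target_genes):
        act_idx = np.flatnonzero(~(set_masks & ~act_member[:, t_i]).any(axis=1))
        rep_idx = np.flatnonzero(~(set_masks & ~rep_member[:, t_i]).any(axis=1))
        if len(act_idx) + len(rep_idx) <= 2:  # only the empty set on both sides
            out[g] = []
            continue
        SA = S[act_idx].astype(np.int16)  # (na, n)
        SI = S[rep_idx].astype(np.int16)  # (ni, n)
        pred = np.sign(SA[:, None, :] - SI[None, :, :])
        fits = np.abs(pred - X[t_i]).mean(axis=2)  # (na, ni)
        # disallow overlapping sides and the (empty, empty) pair
        overlap = (set_masks[act_idx][:, None, :] & set_masks[rep_idx][None, :, :]).any(axis=2)
        fits[overlap] = np.inf
        if act_idx[0] == 0 and rep_idx[0] == 0:
            fits[0, 0] = np.inf
        scored = []
        for a_j, a_c in enumerate(act_idx):
            for i_j, i_c in enumerate(rep_idx):
                f = float(fits[a_j, i_j])
                if f <= fit_cutoff:
                    scored.append(
                        (
                            f,
                            int(set_sizes[a_c] + set_sizes[i_c]),
                            sorted_members[a_c],
                            sorted_members[i_c],
                        )
                    )
        scored.sort()
        out[g] = [
            LocalProgram(g, frozenset(A), frozenset(I), fit_score=f)
            for f, _, A, I in scored[:max_programs_per_gene]
        ]
    return out


def infer_network(
    expr: ExpressionDataset,
    regulators: RegulatorCatalog,
    **params,
) -> RegulatoryNetwork:
    """Infer a network by selecting the best-fitting program per target.

    Un-integrated: every selected program has ``evidence_support = 0``.
    Targets with no candidate under the fit cutoff are omitted and recorded
    in ``network.omitted_targets``.
    """
    candidates = infer_candidate_programs(expr, regulators, **params)
    programs = {g: progs[0] for g, progs in candidates.items() if progs}
    omitted = {g for g, progs in candidates.items() if not progs}
    return RegulatoryNetwork(programs, omitted_targets=omitted)


def edge_f1(
    inferred: RegulatoryNetwork, truth: RegulatoryNetwork
) -> tuple[float, float, float]:
    """Signed edge-level (f1, precision, recall) against a reference network."""
    pred = inferred.signed_edges()
    true = truth.signed_edges()
    if not pred or not true:
        return 0.0, 0.0, 0.0
    tp = len(pred & true)
    precision = tp / len(pred)
    recall = tp / len(true)
    if tp == 0:
        return 0.0, precision, recall
    return 2 * precision * recall / (precision + recall), precision, recall
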