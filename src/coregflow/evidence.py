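"""Evidence integration and evidence-overlap significance.

Candidate local programs from the inference stage are re-scored with
external TF->target (binding/ChIP) and TF<->TF protein-interaction edge
lists: the selected program per gene maximizes

    integrated_score = (1 - fit_score / 2) + lambda * evidence_support

where ``evidence_support`` averages the fraction of the program's
regulator->target edges found in the TF->target evidence with the fraction
of cooperating within-program regulator pairs (co-activator pairs and
co-repressor pairs) found in the PPI evidence (the pair term is dropped
when no side has two regulators).

``evidence_enrichment_test`` quantifies how unlikely the network's overlap
with an evidence layer is under random draws from a defined universe
(hypergeometric upper tail).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

from scipy.stats import hypergeom

from .io import CoregflowError, EvidenceSet, LocalProgram, RegulatoryNetwork

__all__ = [
    "IntegrationParams",
    "evidence_support",
    "integrate_evidence",
    "evidence_enrichment_test",
]


@dataclass(frozen=True)
class IntegrationParams:
    """Evidence weight ``lam`` >= 0 and candidate count considered per gene."""

    lam: float = 1.0
    keep_top: int = 400

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise CoregflowError("lambda must be >= 0")
        if self.keep_top < 1:
            raise CoregflowError("keep_top must be >= 1")


def evidence_support(program: LocalProgram, evidence: EvidenceSet) -> float:
    """Fraction of a program backed by evidence, in [0, 1].

    Mean of (i) the fraction of the program's regulator->target edges in
    the TF->target evidence and (ii) the fraction of cooperating
    within-program regulator pairs — pairs of co-activators plus pairs of
    co-repressors — in the PPI evidence; component (ii) is omitted when no
    side has two regulators.
    """
    return _support(
        program, evidence.tf_target_pairs(), evidence.ppi_pairs()
    )


def _support(
    program: LocalProgram,
    tf_pairs: set[tuple[str, str]],
    ppi: set[tuple[str, str]],
) -> float:
    regs = sorted(program.regulators)
    edge_frac = sum((r, program.target) in tf_pairs for r in regs) / len(regs)
    components = [edge_frac]
    pairs = list(itertools.combinations(sorted(program.activators), 2)) + list(
        itertools.combinations(sorted(program.repressors), 2)
    )
    if pairs:
        components.append(sum(p in ppi for p in pairs) / len(pairs))
    return sum(components) / len(components)


def _tie_key(p: LocalProgram) -> tuple:
    return (len(p.regulators), tuple(sorted(p.activators)), tuple(sorted(p.repressors)))


def integrate_evidence(
    candidates: dict[str, list[LocalProgram]],
    evidence: EvidenceSet,
    params: IntegrationParams = IntegrationParams(),
) -> RegulatoryNetwork:
    """Select, per gene, the candidate maximizing the integrated score.

    Genes with empty candidate lists are omitted (recorded in
    ``omitted_targets``).  Ties break by smaller program size, then
    lexicographic member order — as in the inference stage.
    """
    tf_pairs = evidence.tf_target_pairs()
    ppi_pairs = evidence.ppi_pairs()
    programs: dict[str, LocalProgram] = {}
    omitted: set[str] = set()
    for gene in sorted(candidates):
        cands = candidates[gene][: params.keep_top]
        if not cands:
            omitted.add(gene)
            continue
        scored = []
        for p in cands:
            supp = _support(p, tf_pairs, ppi_pairs)
            score = (1.0 - p.fit_score / 2.0) + params.lam * supp
            scored.append((-score, _tie_key(p), p, supp))
        scored.sort(key=lambda t: (t[0], t[1]))
        _, _, best, supp = scored[0]
        programs[gene] = replace(best, evidence_support=supp)
    return RegulatoryNetwork(programs, omitted_targets=omitted)


def evidence_enrichment_test(
    network: RegulatoryNetwork,
    evidence: EvidenceSet,
    mode: str,
) -> tuple[int, float]:
    """Hypergeometric upper-tail overlap test between network and evidence.

    mode ``ppi``: universe = all unordered pairs of network regulators;
    the network draws its co-regulator pairs (pairs sharing >= 1 program).
    mode ``tfbs``: universe = all (network regulator, network target)
    pairs; the network draws its program edges.  Returns (overlap count,
    P(X >= overlap)).
    """
    if mode == "ppi":
        regs = sorted(network.regulators)
        universe = set(itertools.combinations(regs, 2))
        marked = evidence.ppi_pairs() & universe
        drawn = set()
        for prog in network.programs.values():
            drawn |= set(itertools.combinations(sorted(prog.regulators), 2))
    elif mode == "tfbs":
        regs = sorted(network.regulators)
        tgts = sorted(network.targets)
        universe = {(r, t) for r in regs for t in tgts if r != t}
        marked = evidence.tf_target_pairs() & universe
        drawn = {(r, t) for r, t, _sign in network.signed_edges()}
    else:
        raise CoregflowError(f"unknown enrichment mode {mode!r}")
    if not universe:
        raise CoregflowError("empty evidence universe")
    drawn &= universe
    overlap = len(drawn & marked)
    p = float(hypergeom.sf(overlap - 1, len(universe), len(marked), len(drawn)))
    return overlap, min(p, 1.0)
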