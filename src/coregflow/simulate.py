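"""Synthetic expression compendia with planted cooperative regulatory structure.

The generator emulates the statistical structure of a two-condition
perturbation study mapped onto a reference regulatory network: a small node
of cooperating regulators whose *activity* — not necessarily their own mRNA —
shifts in the stimulated condition, driving activated and repressed target
sets on an additive log-like scale with Gaussian noise.

Generative model
----------------
* regulator activity ``a[r, s] ~ Normal(0, 1)``, plus ``delta`` for planted
  regulators in the stimulated condition (conditions beyond the second act
  as inhibitor arms: the shift is zeroed there);
* regulator mRNA = activity + Normal(0, sigma); with ``decouple_mrna`` the
  planted regulators' mRNA omits the delta shift while their targets still
  respond to the shifted activity (the "influential without mRNA
  up-regulation" phenomenon);
* each target gets activator/repressor sets sampled from the regulator pool;
  the planted regulators co-occur as activators of a dedicated target block;
* target expression ``x[g, s] = sum_A w_r a[r, s] - sum_I w_r a[r, s]
  + Normal(0, sigma)``;
* evidence = a coverage-fraction sample of true TF->target edges plus an
  fpr-fraction of spurious edges; PPI evidence among planted-node pairs with
  the same coverage/fpr corruption.

:func:`simulate_reference` draws a compendium of unstimulated samples (the
stand-in for a cell-line panel) from the same seed-determined true network
and weights, so a network inferred on the compendium can be evaluated
against the query's ground truth.

Seven ordered random sub-streams (activities, weights, topology, noise,
evidence, reference activities, reference noise) are derived from the seed,
so a change confined to one stage does not perturb the others.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CoregflowError,
    EvidenceSet,
    ExpressionDataset,
    LocalProgram,
    RegulatoryNetwork,
)

__all__ = ["SimulationConfig", "GroundTruth", "simulate_dataset", "simulate_reference", "corrupt_evidence"]

BASELINE = "baseline"
STIMULATED = "stimulated"


def _condition_names(n_conditions: int) -> list[str]:
    names = [BASELINE, STIMULATED]
    for i in range(n_conditions - 2):
        names.append(f"stimulated+inhibitor{chr(ord('A') + i)}")
    return names[:n_conditions]


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic compendium.

    Defaults are the generator's reference conditions: 30 regulators,
    300 targets, 20 samples per condition in a two-condition design, a
    3-member planted co-activator node with activity shift ``delta = 2``
    (activity units) and noise ``sigma = 1``.
    """

    n_regulators: int = 30
    n_targets: int = 300
    n_samples_per_condition: int = 20
    n_conditions: int = 2
    planted_node_size: int = 3
    n_reference_samples: int = 206
    delta: float = 2.0
    sigma: float = 1.0
    edge_weight_range: tuple[float, float] = (0.8, 1.2)
    activators_per_target: tuple[int, int] = (1, 2)
    repressors_per_target: tuple[int, int] = (0, 1)
    planted_block_size: int = 30
    evidence_coverage: float = 0.8
    evidence_fpr: float = 0.05
    decouple_mrna: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_regulators, self.n_targets, self.n_samples_per_condition) < 1:
            raise CoregflowError("all counts must be positive")
        if self.n_conditions < 2:
            raise CoregflowError("need at least two conditions")
        if not (0 < self.planted_node_size <= self.n_regulators):
            raise CoregflowError("planted_node_size must be in [1, n_regulators]")
        if self.sigma < 0:
            raise CoregflowError("sigma must be non-negative")
        if not (0 <= self.evidence_coverage <= 1 and 0 <= self.evidence_fpr <= 1):
            raise CoregflowError("coverage and fpr must lie in [0, 1]")
        lo, hi = self.edge_weight_range
        if not (0 < lo <= hi):
            raise CoregflowError("edge_weight_range must be positive and ordered")
        if self.planted_block_size > self.n_targets:
            raise CoregflowError("planted_block_size exceeds n_targets")
        if self.n_reference_samples < 2:
            raise CoregflowError("need at least 2 reference samples")
        for rng_ in (self.activators_per_target, self.repressors_per_target):
            if rng_[0] > rng_[1] or rng_[0] < 0:
                raise CoregflowError("per-target count ranges must be ordered, >= 0")


@dataclass
class GroundTruth:
    """Planted structure behind a simulated dataset."""

    true_network: RegulatoryNetwork
    planted_regulators: set[str]
    true_activity: pd.DataFrame  # regulators x samples
    condition_labels: dict[str, str]
    weights: dict[tuple[str, str], float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_regulators": sorted(self.planted_regulators),
            "condition_labels": self.condition_labels,
            "true_activity": {
                "index": list(self.true_activity.index),
                "columns": list(self.true_activity.columns),
                "values": self.true_activity.to_numpy().tolist(),
            },
            "programs": {
                tgt: {
                    "activators": sorted(p.activators),
                    "repressors": sorted(p.repressors),
                }
                for tgt, p in sorted(self.true_network.programs.items())
            },
            "weights": {f"{r}\t{t}": w for (r, t), w in sorted(self.weights.items())},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(7)
    names = (
        "activities",
        "weights",
        "topology",
        "noise",
        "evidence",
        "ref_activities",
        "ref_noise",
    )
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _build_structure(cfg: SimulationConfig, rng: dict):
    """Identifiers, true network topology and edge weights (seed-determined)."""
    n_r, n_t = cfg.n_regulators, cfg.n_targets
    width_r = max(3, len(str(n_r - 1)))
    width_t = max(3, len(str(n_t - 1)))
    regulators = [f"R{i:0{width_r}d}" for i in range(n_r)]
    targets = [f"G{i:0{width_t}d}" for i in range(n_t)]
    planted = regulators[: cfg.planted_node_size]

    topo = rng["topology"]
    programs: dict[str, LocalProgram] = {}
    planted_set = frozenset(planted)
    for g_i, g in enumerate(targets):
        if g_i < cfg.planted_block_size:
            acts, reps = set(planted_set), set()
        else:
            n_a = int(topo.integers(cfg.activators_per_target[0], cfg.activators_per_target[1] + 1))
            n_i = int(topo.integers(cfg.repressors_per_target[0], cfg.repressors_per_target[1] + 1))
            if n_a + n_i == 0:
                n_a = 1
            picked = topo.choice(n_r, size=n_a + n_i, replace=False)
            acts = {regulators[k] for k in picked[:n_a]}
            reps = {regulators[k] for k in picked[n_a:]}
        programs[g] = LocalProgram(g, frozenset(acts), frozenset(reps))
    true_network = RegulatoryNetwork(programs)

    lo, hi = cfg.edge_weight_range
    weights: dict[tuple[str, str], float] = {}
    wrng = rng["weights"]
    for g in targets:  # fixed iteration order for stream reproducibility
        p = programs[g]
        for r in sorted(p.activators) + sorted(p.repressors):
            weights[(r, g)] = float(wrng.uniform(lo, hi))
    return regulators, targets, planted, true_network, weights


def _target_expression(cfg, regulators, targets, network, weights, activity):
    """Noiseless target expression under the additive linear model."""
    reg_index = {r: i for i, r in enumerate(regulators)}
    x = np.zeros((len(targets), activity.shape[1]))
    for g_i, g in enumerate(targets):
        p = network.programs[g]
        row = np.zeros(activity.shape[1])
        for r in p.activators:
            row += weights[(r, g)] * activity[reg_index[r]]
        for r in p.repressors:
            row -= weights[(r, g)] * activity[reg_index[r]]
        x[g_i] = row
    return x


def simulate_reference(config: SimulationConfig) -> ExpressionDataset:
    """Simulate the reference compendium sharing the query's ground truth.

    Emulates a cell-line expression compendium observed under reference
    conditions: the same true network and edge weights as
    :func:`simulate_dataset` under the same seed, but regulator activities
    drawn Normal(0, 1) with no condition shift and regulator mRNA always
    coupled to activity.  Samples are labelled ``reference``.
    """
    cfg = config
    rng = _streams(cfg.seed)
    regulators, targets, planted, true_network, weights = _build_structure(cfg, rng)
    n_s = cfg.n_reference_samples
    samples = [f"C{j:03d}" for j in range(n_s)]
    activity = rng["ref_activities"].standard_normal((cfg.n_regulators, n_s))
    noise = rng["ref_noise"]
    x_targets = _target_expression(cfg, regulators, targets, true_network, weights, activity)
    if cfg.sigma > 0:
        x_targets = x_targets + noise.normal(0.0, cfg.sigma, size=x_targets.shape)
        x_regs = activity + noise.normal(0.0, cfg.sigma, size=activity.shape)
    else:
        x_regs = activity
    values = pd.DataFrame(
        np.vstack([x_regs, x_targets]), index=regulators + targets, columns=samples
    )
    return ExpressionDataset(values, condition_of={s: "reference" for s in samples})


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionDataset, EvidenceSet, GroundTruth]:
    """Simulate (expression, evidence, ground truth) under ``config``.

    Identical config and seed give byte-identical outputs.  The expression
    matrix stacks regulator mRNA rows (``R###``) over target rows (``G###``).
    """
    cfg = config
    rng = _streams(cfg.seed)
    n_r, n_t, n_spc, n_c = (
        cfg.n_regulators,
        cfg.n_targets,
        cfg.n_samples_per_condition,
        cfg.n_conditions,
    )
    regulators, targets, planted, true_network, weights = _build_structure(cfg, rng)
    conditions = _condition_names(n_c)
    samples = [f"S{c_i * n_spc + j:03d}" for c_i in range(n_c) for j in range(n_spc)]
    condition_labels = {
        s: conditions[i // n_spc] for i, s in enumerate(samples)
    }

    # --- activities -------------------------------------------------------
    activity = rng["activities"].standard_normal((n_r, n_c * n_spc))
    stim_cols = np.array([condition_labels[s] == STIMULATED for s in samples])
    planted_rows = np.arange(cfg.planted_node_size)
    activity[np.ix_(planted_rows, np.flatnonzero(stim_cols))] += cfg.delta

    # --- expression -------------------------------------------------------
    noise = rng["noise"]
    x_targets = _target_expression(cfg, regulators, targets, true_network, weights, activity)
    x_targets += noise.normal(0.0, cfg.sigma, size=x_targets.shape) if cfg.sigma > 0 else 0.0

    mrna_activity = activity.copy()
    if cfg.decouple_mrna:
        mrna_activity[np.ix_(planted_rows, np.flatnonzero(stim_cols))] -= cfg.delta
    x_regs = mrna_activity + (
        noise.normal(0.0, cfg.sigma, size=mrna_activity.shape) if cfg.sigma > 0 else 0.0
    )

    values = pd.DataFrame(
        np.vstack([x_regs, x_targets]), index=regulators + targets, columns=samples
    )
    dataset = ExpressionDataset(values, condition_of=condition_labels)

    truth = GroundTruth(
        true_network=true_network,
        planted_regulators=set(planted),
        true_activity=pd.DataFrame(activity, index=regulators, columns=samples),
        condition_labels=condition_labels,
        weights=weights,
    )

    evidence = corrupt_evidence(
        truth,
        coverage=cfg.evidence_coverage,
        fpr=cfg.evidence_fpr,
        rng=rng["evidence"],
        all_regulators=regulators,
        all_targets=targets,
    )
    return dataset, evidence, truth


def corrupt_evidence(
    truth: GroundTruth,
    coverage: float,
    fpr: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    all_regulators: list[str] | None = None,
    all_targets: list[str] | None = None,
) -> EvidenceSet:
    """Emit a corrupted evidence layer from the ground truth.

    Keeps ``round(coverage * n_true)`` true TF->target edges (sampled
    without replacement) and adds ``round(fpr * n_true)`` spurious edges
    drawn from non-true regulator/target pairs; the planted node's pairwise
    PPIs are corrupted the same way.  Deterministic under ``seed``.
    """
    if not (0 <= coverage <= 1 and 0 <= fpr <= 1):
        raise CoregflowError("coverage and fpr must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    network = truth.true_network
    regulators = all_regulators or sorted(network.regulators)
    targets = all_targets or sorted(network.targets)

    true_edges = sorted({(r, t) for r, t, _ in network.signed_edges()})
    n_true = len(true_edges)
    n_keep = int(round(coverage * n_true))
    keep_idx = rng.choice(n_true, size=n_keep, replace=False) if n_true else []
    kept = {true_edges[i] for i in np.sort(np.asarray(keep_idx, dtype=int))}

    n_fp = int(round(fpr * n_true))
    true_set = set(true_edges)
    spurious: set[tuple[str, str]] = set()
    while len(spurious) < n_fp:
        r = regulators[int(rng.integers(len(regulators)))]
        t = targets[int(rng.integers(len(targets)))]
        if (r, t) not in true_set:
            spurious.add((r, t))

    tf_edges = {(r, t, "sim_true") for r, t in kept} | {
        (r, t, "sim_fp") for r, t in spurious
    }

    planted = sorted(truth.planted_regulators)
    true_ppi = sorted(itertools.combinations(planted, 2))
    n_ppi = len(true_ppi)
    n_ppi_keep = int(round(coverage * n_ppi))
    ppi_keep_idx = rng.choice(n_ppi, size=n_ppi_keep, replace=False) if n_ppi else []
    ppi_kept = {true_ppi[i] for i in np.sort(np.asarray(ppi_keep_idx, dtype=int))}
    n_ppi_fp = int(round(fpr * n_ppi))
    all_pairs = [p for p in itertools.combinations(sorted(regulators), 2)
                 if p not in set(true_ppi)]
    ppi_fp: set[tuple[str, str]] = set()
    while all_pairs and len(ppi_fp) < n_ppi_fp:
        ppi_fp.add(all_pairs[int(rng.integers(len(all_pairs)))])

    ppi_edges = {(a, b, "sim_true") for a, b in ppi_kept} | {
        (a, b, "sim_fp") for a, b in ppi_fp
    }
    return EvidenceSet(tf_edges, ppi_edges)
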