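"""Domain types and tabular I/O.

All tabular files are UTF-8, tab-separated, ``.`` decimal, ``NA`` missing
marker.  Identifiers are case-sensitive opaque strings; no symbol aliasing
is attempted.

Formats
-------
expression matrix
    header row of sample ids, first column gene ids, numeric cells.
design table
    two columns ``sample`` / ``condition`` (header optional-free: exactly
    two tab-separated columns per row, first row treated as header if it
    is ``sample<TAB>condition``).
evidence edge lists
    three columns: ``regulator / target / source`` for TF->target edges and
    ``regulatorA / regulatorB / source`` for protein-protein interactions.
network program table
    one row per target gene: ``target, activators (';'-joined),
    repressors (';'-joined), fit_score, evidence_support``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CoregflowError",
    "MalformedFileError",
    "DuplicateIdError",
    "NonNumericError",
    "DesignMismatchError",
    "MissingValueError",
    "ExpressionDataset",
    "RegulatorCatalog",
    "EvidenceSet",
    "LocalProgram",
    "RegulatoryNetwork",
    "read_expression",
    "read_design",
    "read_regulators",
    "read_evidence",
    "write_expression",
    "write_network",
    "read_network",
]


class CoregflowError(Exception):
    """Base class for all package errors."""


class MalformedFileError(CoregflowError):
    """File structure (header, column count) is not as documented."""


class DuplicateIdError(CoregflowError):
    """Duplicate gene or sample identifiers."""


class NonNumericError(CoregflowError):
    """A matrix cell could not be parsed as a finite real or NA."""


class DesignMismatchError(CoregflowError):
    """Design table refers to samples absent from the matrix."""


class MissingValueError(CoregflowError):
    """Missing expression values under the 'fail' imputation policy."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """Genes x samples log-scale expression with optional condition labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.
    condition_of
        Mapping sample id -> condition label; when attached, every sample
        must be labelled.
    """

    values: pd.DataFrame
    condition_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dups = sorted(idx[idx.duplicated()].unique())
            raise DuplicateIdError(f"duplicate gene ids: {dups[:5]}")
        if cols.duplicated().any():
            dups = sorted(cols[cols.duplicated()].unique())
            raise DuplicateIdError(f"duplicate sample ids: {dups[:5]}")
        if not np.issubdtype(self.values.to_numpy().dtype, np.floating):
            self.values = self.values.astype(float)
        if self.condition_of is not None:
            missing = [s for s in cols if s not in self.condition_of]
            if missing:
                raise DesignMismatchError(
                    f"samples without condition label: {missing[:5]}"
                )
            unknown = [s for s in self.condition_of if s not in set(cols)]
            if unknown:
                raise DesignMismatchError(
                    f"design samples not in matrix: {unknown[:5]}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_of(self, condition: str) -> list[str]:
        """Sample ids carrying the given condition label."""
        if self.condition_of is None:
            raise DesignMismatchError("no design attached")
        return [s for s in self.sample_ids if self.condition_of[s] == condition]

    def standardized(self) -> "ExpressionDataset":
        """Per-gene centred/scaled copy (unbiased SD; zero-variance rows -> 0)."""
        x = self.values.to_numpy(dtype=float)
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (x - mu) / sd
        z[~np.isfinite(z)] = 0.0
        return ExpressionDataset(
            pd.DataFrame(z, index=self.values.index, columns=self.values.columns),
            condition_of=dict(self.condition_of) if self.condition_of else None,
        )


@dataclass(frozen=True)
class RegulatorCatalog:
    """Set of gene ids designated as transcription factors / co-factors."""

    regulator_ids: frozenset[str]

    def restrict_to(self, dataset: ExpressionDataset) -> "RegulatorCatalog":
        """Drop regulators absent from the expression matrix (with a warning)."""
        present = self.regulator_ids & set(dataset.gene_ids)
        dropped = self.regulator_ids - present
        if dropped:
            warnings.warn(
                f"{len(dropped)} regulator(s) absent from the expression matrix "
                f"were dropped (e.g. {sorted(dropped)[:3]})",
                stacklevel=2,
            )
        return RegulatorCatalog(frozenset(present))

    def __len__(self) -> int:
        return len(self.regulator_ids)

    def __iter__(self):
        return iter(sorted(self.regulator_ids))


def _norm_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class EvidenceSet:
    """External regulatory evidence.

    ``tf_target_edges`` holds directed (regulator, target, source_tag)
    triples pooling binding-site and ChIP sources; ``ppi_edges`` holds
    unordered regulator pairs stored as lexicographically sorted
    (a, b, source_tag) triples.  Self-loop PPIs are never stored.
    """

    tf_target_edges: set[tuple[str, str, str]] = field(default_factory=set)
    ppi_edges: set[tuple[str, str, str]] = field(default_factory=set)
    n_rejected_ppi: int = 0

    def __post_init__(self) -> None:
        for a, b, tag in self.tf_target_edges | self.ppi_edges:
            if not tag:
                raise CoregflowError("empty source_tag in evidence")
        self.ppi_edges = {(*_norm_pair(a, b), tag) for a, b, tag in self.ppi_edges}
        if any(a == b for a, b, _ in self.ppi_edges):
            raise CoregflowError("self-loop in ppi_edges")

    def tf_target_pairs(self) -> set[tuple[str, str]]:
        return {(r, t) for r, t, _ in self.tf_target_edges}

    def ppi_pairs(self) -> set[tuple[str, str]]:
        return {(a, b) for a, b, _ in self.ppi_edges}

    def has_ppi(self, a: str, b: str) -> bool:
        return _norm_pair(a, b) in self.ppi_pairs()

    def has_tf_target(self, regulator: str, target: str) -> bool:
        return (regulator, target) in self.tf_target_pairs()


@dataclass(frozen=True)
class LocalProgram:
    """Local regulatory program of one target gene.

    The pair (activators A, repressors I) of cooperating regulators that
    explains the target's discrete expression, with the discrete fit score
    (mean absolute prediction error, in [0, 2]; 0 = perfect) and the
    fraction of the program supported by external evidence.
    """

    target: str
    activators: frozenset[str]
    repressors: frozenset[str]
    fit_score: float = 0.0
    evidence_support: float = 0.0

    def __post_init__(self) -> None:
        if self.activators & self.repressors:
            raise CoregflowError(
                f"{self.target}: activators and repressors overlap"
            )
        if not (self.activators | self.repressors):
            raise CoregflowError(f"{self.target}: empty program")
        if not (0.0 <= self.fit_score <= 2.0):
            raise CoregflowError(f"{self.target}: fit_score outside [0, 2]")
        if not (0.0 <= self.evidence_support <= 1.0):
            raise CoregflowError(f"{self.target}: evidence_support outside [0, 1]")

    @property
    def regulators(self) -> frozenset[str]:
        return self.activators | self.repressors


@dataclass
class RegulatoryNetwork:
    """Mapping target gene -> LocalProgram, plus the derived regulon view."""

    programs: dict[str, LocalProgram]
    omitted_targets: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for tgt, prog in self.programs.items():
            if prog.target != tgt:
                raise CoregflowError(f"program key {tgt} != target {prog.target}")

    def regulon_view(self) -> dict[str, tuple[set[str], set[str]]]:
        """regulator -> (A^r genes it activates, I^r genes it represses)."""
        view: dict[str, tuple[set[str], set[str]]] = {}
        for tgt, prog in self.programs.items():
            for r in prog.activators:
                view.setdefault(r, (set(), set()))[0].add(tgt)
            for r in prog.repressors:
                view.setdefault(r, (set(), set()))[1].add(tgt)
        return view

    @property
    def regulators(self) -> set[str]:
        out: set[str] = set()
        for prog in self.programs.values():
            out |= prog.regulators
        return out

    @property
    def targets(self) -> set[str]:
        return set(self.programs)

    def n_interactions(self) -> int:
        return sum(len(p.regulators) for p in self.programs.values())

    def summary(self) -> dict[str, int]:
        return {
            "n_regulators": len(self.regulators),
            "n_targets": len(self.programs),
            "n_interactions": self.n_interactions(),
        }

    def signed_edges(self) -> set[tuple[str, str, int]]:
        """(regulator, target, +1/-1) triples; +1 for activation."""
        edges: set[tuple[str, str, int]] = set()
        for tgt, prog in self.programs.items():
            edges |= {(r, tgt, +1) for r in prog.activators}
            edges |= {(r, tgt, -1) for r in prog.repressors}
        return edges


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_NA = "NA"


def read_design(path: str | Path) -> dict[str, str]:
    """Read a two-column sample -> condition table (header row required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise MalformedFileError(
            f"design table must have 2 columns, found {df.shape[1]}"
        )
    samples = df.iloc[:, 0]
    if samples.duplicated().any():
        raise DuplicateIdError("duplicate sample in design table")
    return dict(zip(samples, df.iloc[:, 1]))


def read_expression(
    path: str | Path,
    design_path: str | Path | None = None,
    missing_policy: str = "fail",
) -> ExpressionDataset:
    """Read a genes x samples TSV matrix, optionally attaching a design.

    ``missing_policy`` is ``fail`` (any NA raises :class:`MissingValueError`)
    or ``gene-mean`` (NA cells replaced by the gene's row mean).
    """
    if missing_policy not in ("fail", "gene-mean"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=[_NA], keep_default_na=False)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise MalformedFileError(str(exc)) from exc
    if df.shape[1] == 0:
        raise MalformedFileError("expression matrix has no sample columns")
    if df.columns.str.startswith("Unnamed").any():
        raise MalformedFileError("malformed header: unnamed sample column")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise NonNumericError(f"non-numeric expression cell: {exc}") from exc
    if np.isinf(df.to_numpy()).any():
        raise NonNumericError("non-finite expression value")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    if df.isna().any().any():
        if missing_policy == "fail":
            raise MissingValueError(
                "missing expression values present; use missing_policy='gene-mean'"
            )
        row_means = df.mean(axis=1, skipna=True)
        df = df.apply(lambda row: row.fillna(row_means[row.name]), axis=1)

    condition_of = read_design(design_path) if design_path is not None else None
    return ExpressionDataset(df, condition_of=condition_of)


def write_expression(dataset: ExpressionDataset, path: str | Path) -> None:
    dataset.values.to_csv(path, sep="\t", float_format="%.10g", index_label="gene")


def read_regulators(path: str | Path) -> RegulatorCatalog:
    """Read a regulator catalog: one gene identifier per line."""
    ids = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    return RegulatorCatalog(frozenset(ids))


_TF_COLS = ("regulator", "target", "source")
_PPI_COLS = ("regulatorA", "regulatorB", "source")


def read_evidence(
    tf_target_path: str | Path | None,
    ppi_path: str | Path | None,
) -> EvidenceSet:
    """Read TF->target and PPI edge lists into a deduplicated EvidenceSet.

    Self-loop PPI rows are rejected (counted in ``n_rejected_ppi`` and
    reported via a warning); repeated rows collapse to one edge.
    """
    tf_edges: set[tuple[str, str, str]] = set()
    ppi_edges: set[tuple[str, str, str]] = set()
    n_rejected = 0
    if tf_target_path is not None:
        df = pd.read_csv(tf_target_path, sep="\t", dtype=str)
        if tuple(df.columns) != _TF_COLS:
            raise MalformedFileError(
                f"TF-target evidence columns must be {_TF_COLS}, got {tuple(df.columns)}"
            )
        tf_edges = {tuple(row) for row in df.itertuples(index=False)}
    if ppi_path is not None:
        df = pd.read_csv(ppi_path, sep="\t", dtype=str)
        if tuple(df.columns) != _PPI_COLS:
            raise MalformedFileError(
                f"PPI evidence columns must be {_PPI_COLS}, got {tuple(df.columns)}"
            )
        for a, b, tag in df.itertuples(index=False):
            if a == b:
                n_rejected += 1
                continue
            ppi_edges.add((*_norm_pair(a, b), tag))
    if n_rejected:
        warnings.warn(f"rejected {n_rejected} self-loop PPI row(s)", stacklevel=2)
    return EvidenceSet(tf_edges, ppi_edges, n_rejected_ppi=n_rejected)


def write_evidence(evidence: EvidenceSet, tf_target_path: str | Path, ppi_path: str | Path) -> None:
    tf = pd.DataFrame(sorted(evidence.tf_target_edges), columns=list(_TF_COLS))
    tf.to_csv(tf_target_path, sep="\t", index=False)
    ppi = pd.DataFrame(sorted(evidence.ppi_edges), columns=list(_PPI_COLS))
    ppi.to_csv(ppi_path, sep="\t", index=False)


_NETWORK_COLS = ("target", "activators", "repressors", "fit_score", "evidence_support")


def write_network(network: RegulatoryNetwork, path: str | Path) -> None:
    """Serialize programs to a TSV program table (exact float round-trip)."""
    rows = []
    for tgt in sorted(network.programs):
        p = network.programs[tgt]
        rows.append(
            "\t".join(
                [
                    tgt,
                    ";".join(sorted(p.activators)),
                    ";".join(sorted(p.repressors)),
                    repr(float(p.fit_score)),
                    repr(float(p.evidence_support)),
                ]
            )
        )
    Path(path).write_text("\t".join(_NETWORK_COLS) + "\n" + "".join(r + "\n" for r in rows))


def _parse_idset(fieldtext: str) -> frozenset[str]:
    return frozenset(x for x in fieldtext.split(";") if x)


def read_network(path: str | Path) -> RegulatoryNetwork:
    lines = Path(path).read_text().splitlines()
    if not lines or tuple(lines[0].split("\t")) != _NETWORK_COLS:
        raise MalformedFileError(f"network table header must be {_NETWORK_COLS}")
    programs: dict[str, LocalProgram] = {}
    for ln in lines[1:]:
        if not ln:
            continue
        parts = ln.split("\t")
        if len(parts) != 5:
            raise MalformedFileError(f"bad network row: {ln!r}")
        tgt, act, rep, fit, supp = parts
        if tgt in programs:
            raise DuplicateIdError(f"duplicate target {tgt} in network table")
        programs[tgt] = LocalProgram(
            target=tgt,
            activators=_parse_idset(act),
            repressors=_parse_idset(rep),
            fit_score=float(fit),
            evidence_support=float(supp),
        )
    return RegulatoryNetwork(programs)
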