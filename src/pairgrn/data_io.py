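"""Readers and writers for the tab-delimited DREAM-style file dialects.

Three dialects are supported:

* **Expression matrix** — TSV with a header row of gene names followed by
  one row of floats per steady-state experiment (the DREAM4 "Size 100
  Multifactorial" layout).
* **Edge list** — three columns ``regulator TAB target TAB value``; used
  both for gold standards (value in {0, 1}) and for ranked predictions
  (value = confidence weight).
* **TF list** — one regulator gene name per line (DREAM5 layout).

Matrix orientation is fixed throughout the package: in a weight matrix
``W``, entry ``W[j, i]`` is the confidence that gene ``j`` directly
regulates gene ``i`` (row = regulator, column = target), so per-target
normalization acts on columns.  Gene indices are 0-based internally; files
always carry gene names.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import PairgrnError

__all__ = [
    "ParseError",
    "ExpressionData",
    "EdgeSet",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_tf_list",
    "read_gold_standard",
    "read_predictions",
    "write_gold_standard",
    "write_predictions",
]


class ParseError(PairgrnError, ValueError):
    """A DREAM-dialect file violates its format contract."""


@dataclasses.dataclass
class ExpressionData:
    """Steady-state expression levels from multifactorial perturbations.

    Attributes
    ----------
    gene_names:
        Unique identifiers, one per matrix column.
    values:
        ``(m, n)`` array; ``values[k, i]`` is the steady-state level of
        gene ``i`` in experiment ``k``.  Each experiment corresponds to one
        random simultaneous perturbation of all basal activations (one
        "patient" profile).
    """

    gene_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape[1] != len(self.gene_names):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.gene_names)} gene names"
            )
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValueError("gene names must be unique")
        if self.values.shape[0] < 2:
            raise ValueError("insufficient experiments: need m >= 2")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def m(self) -> int:
        """Number of experiments (rows)."""
        return self.values.shape[0]

    @property
    def n(self) -> int:
        """Number of genes (columns)."""
        return self.values.shape[1]

    def column(self, i: int) -> np.ndarray:
        return self.values[:, i]


@dataclasses.dataclass
class EdgeSet:
    """Directed edges with 0/1 labels; self-pairs are forbidden.

    ``labels`` maps ``(regulator_index, target_index)`` to 0 or 1.  Pairs
    absent from the mapping are treated as unlabeled (label 0 during
    evaluation, matching the DREAM convention that unlisted pairs are
    non-edges).
    """

    labels: dict[tuple[int, int], int]
    n: int

    def __post_init__(self) -> None:
        for (j, i), lab in self.labels.items():
            if j == i:
                raise ValueError(f"self-pair ({j}, {i}) not allowed")
            if not (0 <= j < self.n and 0 <= i < self.n):
                raise ValueError(f"edge ({j}, {i}) outside [0, {self.n})")
            if lab not in (0, 1):
                raise ValueError(f"label for ({j}, {i}) must be 0 or 1, got {lab}")

    @property
    def positives(self) -> set[tuple[int, int]]:
        return {pair for pair, lab in self.labels.items() if lab == 1}

    def __len__(self) -> int:
        return len(self.labels)


def _read_lines(path: str | Path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.rstrip("\n").rstrip("\r") for line in fh]


def read_expression_matrix(path: str | Path) -> ExpressionData:
    """Parse a DREAM4-style expression TSV (header of gene names, float rows).

    Raises
    ------
    ParseError
        On ragged rows or non-numeric cells (the offending 1-based line is
        named) and when fewer than two experiment rows are present.
    """
    lines = [ln for ln in _read_lines(path) if ln.strip() != ""]
    if not lines:
        raise ParseError(f"{path}: empty file")
    names = lines[0].split("\t")
    if any(not nm.strip() for nm in names):
        raise ParseError(f"{path}: blank gene name in header")
    n = len(names)
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != n:
            raise ParseError(
                f"{path}: line {lineno}: expected {n} columns, found {len(cells)}"
            )
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-numeric cell ({exc})") from None
    if len(rows) < 2:
        raise ParseError(f"{path}: insufficient experiments (need >= 2 data rows)")
    return ExpressionData(gene_names=[nm.strip() for nm in names], values=np.array(rows))


def write_expression_matrix(data: ExpressionData, path: str | Path) -> None:
    """Write ``data`` in the DREAM4 expression TSV dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(data.gene_names) + "\n")
        for row in data.values:
            fh.write("\t".join(format(v, ".10g") for v in row) + "\n")


def read_tf_list(path: str | Path, gene_names: Sequence[str]) -> list[int]:
    """Read a one-name-per-line regulator list into gene indices.

    Order is preserved and duplicates are dropped.  Unknown names raise a
    ParseError listing every offender; an empty file raises "no regulators".
    """
    index = {nm: i for i, nm in enumerate(gene_names)}
    seen: set[str] = set()
    out: list[int] = []
    unknown: list[str] = []
    for line in _read_lines(path):
        nm = line.strip()
        if not nm or nm in seen:
            continue
        seen.add(nm)
        if nm in index:
            out.append(index[nm])
        else:
            unknown.append(nm)
    if unknown:
        raise ParseError(f"{path}: unknown regulator names: {', '.join(unknown)}")
    if not out:
        raise ParseError(f"{path}: no regulators")
    return out


def _parse_edge_lines(
    path: str | Path, gene_names: Sequence[str]
) -> Iterable[tuple[int, int, float]]:
    index = {nm: i for i, nm in enumerate(gene_names)}
    for lineno, line in enumerate(_read_lines(path), start=1):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != 3:
            raise ParseError(f"{path}: line {lineno}: expected 3 columns, found {len(cells)}")
        reg, targ, val = cells
        for nm in (reg, targ):
            if nm not in index:
                raise ParseError(f"{path}: line {lineno}: unknown gene name {nm!r}")
        try:
            value = float(val)
        except ValueError:
            raise ParseError(f"{path}: line {lineno}: non-numeric value {val!r}") from None
        yield index[reg], index[targ], value


def read_gold_standard(path: str | Path, gene_names: Sequence[str]) -> EdgeSet:
    """Read a gold-standard edge list ``regulator TAB target TAB {0,1}``."""
    labels: dict[tuple[int, int], int] = {}
    for j, i, value in _parse_edge_lines(path, gene_names):
        if value not in (0.0, 1.0):
            raise ParseError(f"{path}: gold-standard label must be 0 or 1, got {value}")
        labels[(j, i)] = int(value)
    return EdgeSet(labels=labels, n=len(gene_names))


def read_predictions(
    path: str | Path, gene_names: Sequence[str]
) -> list[tuple[int, int, float]]:
    """Read a ranked prediction file; returns (regulator, target, weight) in file order."""
    return list(_parse_edge_lines(path, gene_names))


def write_gold_standard(
    edges: EdgeSet, gene_names: Sequence[str], path: str | Path
) -> None:
    """Write labeled edges, positives first, in deterministic index order."""
    ordered = sorted(edges.labels.items(), key=lambda kv: (-kv[1], kv[0]))
    with open(path, "w", encoding="utf-8") as fh:
        for (j, i), lab in ordered:
            fh.write(f"{gene_names[j]}\t{gene_names[i]}\t{lab}\n")


def write_predictions(
    W: np.ndarray,
    gene_names: Sequence[str],
    path: str | Path,
    max_edges: int = 100_000,
) -> int:
    """Write the ranked edge list implied by weight matrix ``W``.

    Lines are ``regulator TAB target TAB weight`` sorted by weight,
    strictly non-increasing; ties are broken by ascending (regulator index,
    target index) so the output is a total order.  Self-edges are excluded
    and at most ``max_edges`` lines are written.  Returns the number of
    lines written.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if W.shape != (n, n):
        raise ValueError("weight matrix must be square")
    if not np.all(np.isfinite(W)):
        raise ValueError("weight matrix must be finite")
    if max_edges < 1:
        raise ValueError("max_edges must be positive")
    regs, targs = np.nonzero(~np.eye(n, dtype=bool))
    weights = W[regs, targs]
    # stable sort on -weight keeps the (regulator, target) lexicographic
    # enumeration order inside each tie group
    order = np.argsort(-weights, kind="stable")[:max_edges]
    with open(path, "w", encoding="utf-8") as fh:
        for idx in order:
            j, i = int(regs[idx]), int(targs[idx])
            fh.write(f"{gene_names[j]}\t{gene_names[i]}\t{format(weights[idx], '.10g')}\n")
    return len(order)
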