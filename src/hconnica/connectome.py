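"""Connectome containers and file I/O.

A connectome is a square, symmetric, zero-diagonal weighted adjacency matrix
over a fixed set of labelled brain regions (nodes).  Three modalities are
distinguished:

``FC``
    Functional connectivity: Pearson correlations between regional fMRI time
    courses, signed, in [-1, 1].
``SC_RAW``
    Structural connectivity: non-negative streamline weights from diffusion
    tractography (possibly log-transformed, still non-negative).
``SC_CORR``
    Structural correlation: Pearson correlations between rows of a structural
    connectome, in [-1, 1].

Files are plain TSV matrices with an optional ``#labels:`` header line, so
every artifact stays human-inspectable.  Cohorts are described by a CSV
manifest (subject_id, condition, fc_path, sc_path) and a node->RSN partition
CSV.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: maximum tolerated |M - M.T| before a matrix is rejected as asymmetric
SYMMETRY_TOL = 1e-9


class Modality(str, enum.Enum):
    FC = "FC"
    SC_RAW = "SC_RAW"
    SC_CORR = "SC_CORR"


class ConnectomeError(ValueError):
    """Base class for connectome validation failures."""


class ShapeError(ConnectomeError):
    pass


class SymmetryError(ConnectomeError):
    pass


class RangeError(ConnectomeError):
    pass


def _default_labels(n: int) -> list[str]:
    width = len(str(n - 1)) if n > 1 else 1
    return [f"N{i:0{width}d}" for i in range(n)]


@dataclass
class Connectome:
    """A validated single-subject connectivity matrix.

    On construction the matrix is symmetrized (exact averaging with its
    transpose, provided the asymmetry is within :data:`SYMMETRY_TOL`), the
    diagonal is forced to zero, and modality-specific value ranges are
    enforced.
    """

    matrix: np.ndarray
    node_labels: list[str] = field(default_factory=list)
    modality: Modality = Modality.FC
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ShapeError(f"shape error: expected square matrix, got {m.shape}")
        if not np.isfinite(m).all():
            raise RangeError("range error: matrix contains non-finite values")
        asym = np.abs(m - m.T).max() if m.size else 0.0
        if asym > SYMMETRY_TOL:
            raise SymmetryError(
                f"symmetry error: max |M - M.T| = {asym:.3g} exceeds {SYMMETRY_TOL:g}"
            )
        m = (m + m.T) / 2.0
        np.fill_diagonal(m, 0.0)
        self.modality = Modality(self.modality)
        if self.modality in (Modality.FC, Modality.SC_CORR):
            if m.min() < -1.0 or m.max() > 1.0:
                raise RangeError(
                    f"range error: {self.modality.value} values must lie in [-1, 1]; "
                    f"observed [{m.min():.4g}, {m.max():.4g}]"
                )
        else:  # SC_RAW
            if m.min() < 0.0:
                raise RangeError(
                    f"range error: SC_RAW weights must be >= 0; min = {m.min():.4g}"
                )
        if not self.node_labels:
            self.node_labels = _default_labels(m.shape[0])
        self.node_labels = [str(x) for x in self.node_labels]
        if len(self.node_labels) != m.shape[0]:
            raise ShapeError(
                f"shape error: {len(self.node_labels)} labels for {m.shape[0]} nodes"
            )
        self.matrix = m

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    def permuted(self, order: Sequence[int]) -> "Connectome":
        """Return a copy with nodes reordered by ``order``."""
        order = list(order)
        return Connectome(
            matrix=self.matrix[np.ix_(order, order)],
            node_labels=[self.node_labels[i] for i in order],
            modality=self.modality,
            subject_id=self.subject_id,
            condition=self.condition,
        )


_LABEL_PREFIX = "#labels:"


def read_connectome(
    path: str | os.PathLike,
    modality: Modality | str,
    subject_id: str = "",
    condition: str = "",
) -> Connectome:
    """Read a TSV matrix file (optional ``#labels:`` header) as a Connectome.

    Node order is the file order; it is never changed silently.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        labels: list[str] = []
        if first.startswith(_LABEL_PREFIX):
            labels = first[len(_LABEL_PREFIX):].strip().split("\t")
            rest = fh.read()
        else:
            rest = first + fh.read()
    rows = [line.split("\t") for line in rest.strip().splitlines() if line.strip()]
    if not rows:
        raise ShapeError(f"shape error: empty matrix file {path}")
    try:
        m = np.array(rows, dtype=float)
    except ValueError as exc:
        raise ConnectomeError(f"could not parse numeric matrix from {path}: {exc}")
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ShapeError(f"shape error: {path} parses to {m.shape}, expected square")
    return Connectome(
        matrix=m,
        node_labels=labels,
        modality=Modality(modality),
        subject_id=subject_id,
        condition=condition,
    )


def write_connectome(c: Connectome, path: str | os.PathLike) -> Path:
    """Write a Connectome as TSV with a ``#labels:`` header.

    Values are printed with ``%.17g`` so read/write round-trips are exact at
    float64 precision.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_LABEL_PREFIX + " " + "\t".join(c.node_labels) + "\n")
        for row in c.matrix:
            fh.write("\t".join(f"{x:.17g}" for x in row) + "\n")
    return path


MANIFEST_COLUMNS = ("subject_id", "condition", "fc_path", "sc_path")


@dataclass
class CohortManifest:
    """Cohort table: one row per (subject, condition) profile."""

    frame: pd.DataFrame
    base_dir: Path = Path(".")

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ConnectomeError(f"manifest missing column(s): {missing}")
        if len(self.frame) == 0:
            raise ConnectomeError("manifest is empty")
        dup = self.frame.duplicated(subset=["subject_id", "condition"])
        if dup.any():
            bad = self.frame.loc[dup, ["subject_id", "condition"]].values.tolist()
            raise ConnectomeError(f"duplicate (subject, condition) rows: {bad}")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def subjects(self) -> list[str]:
        return self.frame["subject_id"].astype(str).tolist()

    @property
    def conditions(self) -> list[str]:
        return self.frame["condition"].astype(str).tolist()

    @property
    def condition_set(self) -> list[str]:
        seen: list[str] = []
        for c in self.conditions:
            if c not in seen:
                seen.append(c)
        return seen

    def resolve(self, rel: str) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else self.base_dir / p


def read_cohort_manifest(
    path: str | os.PathLike, check_paths: bool = True
) -> CohortManifest:
    """Load a cohort manifest CSV; paths are resolved relative to the file."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise ConnectomeError(f"manifest {path} is empty")
    manifest = CohortManifest(frame=frame, base_dir=path.parent)
    if check_paths:
        for col in ("fc_path", "sc_path"):
            for rel in manifest.frame[col]:
                p = manifest.resolve(rel)
                if not p.exists():
                    raise ConnectomeError(f"manifest path not found: {p}")
    return manifest


@dataclass
class NodePartition:
    """Assignment of each node label to a resting-state network (RSN)."""

    node_labels: list[str]
    rsn: list[str]

    def __post_init__(self) -> None:
        if len(self.node_labels) != len(self.rsn):
            raise ConnectomeError("partition: labels and RSN lists differ in length")
        if len(set(self.node_labels)) != len(self.node_labels):
            raise ConnectomeError("partition: duplicate node labels")

    @property
    def mapping(self) -> dict[str, str]:
        return dict(zip(self.node_labels, self.rsn))

    @property
    def rsn_names(self) -> list[str]:
        seen: list[str] = []
        for r in self.rsn:
            if r not in seen:
                seen.append(r)
        return seen

    def validate_against(self, labels: Sequence[str]) -> None:
        """Every connectome node must be assigned exactly once."""
        if list(labels) != self.node_labels:
            if set(labels) != set(self.node_labels):
                raise ConnectomeError(
                    "partition does not cover the connectome node set"
                )
            raise ConnectomeError(
                "partition node order differs from connectome node order"
            )


def read_node_partition(path: str | os.PathLike) -> NodePartition:
    frame = pd.read_csv(path, dtype=str)
    cols = list(frame.columns)
    if not {"node_label", "rsn"}.issubset(cols):
        raise ConnectomeError("partition CSV must have columns node_label,rsn")
    return NodePartition(
        node_labels=frame["node_label"].tolist(), rsn=frame["rsn"].tolist()
    )


def write_node_partition(p: NodePartition, path: str | os.PathLike) -> Path:
    path = Path(path)
    pd.DataFrame({"node_label": p.node_labels, "rsn": p.rsn}).to_csv(
        path, index=False
    )
    return path
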