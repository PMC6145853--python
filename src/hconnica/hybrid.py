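"""Hybrid profile assembly: edge vectorization and de-vectorization.

Each subject-condition profile is a single row vector: the upper-triangular
FC edges (all node pairs i<j, row-major) concatenated with the masked
structural-correlation edges.  The cohort of such rows is the hybrid matrix
that the decomposition operates on.  The :class:`EdgeIndex` records the exact
column ordering so any trait vector can be mapped back onto symmetric
matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .connectome import Connectome, ConnectomeError, Modality, ShapeError
from .sc_transform import EdgeMask, upper_pairs


@dataclass
class EdgeIndex:
    """Canonical column ordering of a hybrid vector.

    The FC block lists all i<j pairs row-major (length n(n-1)/2); the SC
    block lists the population-masked pairs in the same canonical order.
    """

    n_nodes: int
    fc_pairs: np.ndarray  # (L_FC, 2) int
    sc_pairs: np.ndarray  # (L_SC, 2) int

    def __post_init__(self) -> None:
        self.fc_pairs = np.asarray(self.fc_pairs, dtype=int).reshape(-1, 2)
        self.sc_pairs = np.asarray(self.sc_pairs, dtype=int).reshape(-1, 2)
        expected = self.n_nodes * (self.n_nodes - 1) // 2
        if len(self.fc_pairs) != expected:
            raise ShapeError(
                f"EdgeIndex: FC block has {len(self.fc_pairs)} pairs, expected "
                f"n(n-1)/2 = {expected}"
            )

    @classmethod
    def from_mask(cls, mask: EdgeMask) -> "EdgeIndex":
        return cls(
            n_nodes=mask.n_nodes,
            fc_pairs=upper_pairs(mask.n_nodes),
            sc_pairs=mask.pairs(),
        )

    @property
    def l_fc(self) -> int:
        return len(self.fc_pairs)

    @property
    def l_sc(self) -> int:
        return len(self.sc_pairs)

    @property
    def length(self) -> int:
        return self.l_fc + self.l_sc

    @property
    def fc_slice(self) -> slice:
        return slice(0, self.l_fc)

    @property
    def sc_slice(self) -> slice:
        return slice(self.l_fc, self.length)


def vectorize_profile(
    fc: Connectome, sc_corr: Connectome, idx: EdgeIndex
) -> np.ndarray:
    """Concatenate FC upper-triangle and masked SC-corr edges into one row."""
    if fc.n_nodes != idx.n_nodes or sc_corr.n_nodes != idx.n_nodes:
        raise ShapeError(
            f"vectorize_profile: node counts (FC {fc.n_nodes}, SC {sc_corr.n_nodes}) "
            f"do not match EdgeIndex ({idx.n_nodes})"
        )
    if fc.node_labels != sc_corr.node_labels:
        raise ConnectomeError(
            f"vectorize_profile: node-order mismatch between FC and SC for "
            f"subject {fc.subject_id!r}"
        )
    v = np.empty(idx.length)
    v[idx.fc_slice] = fc.matrix[idx.fc_pairs[:, 0], idx.fc_pairs[:, 1]]
    v[idx.sc_slice] = sc_corr.matrix[idx.sc_pairs[:, 0], idx.sc_pairs[:, 1]]
    return v


def devectorize_trait(
    v: np.ndarray, idx: EdgeIndex
) -> tuple[np.ndarray, np.ndarray]:
    """Split a hybrid vector into symmetric FC-part and SC-part matrices.

    The SC part is zero outside the population edge mask.
    """
    v = np.asarray(v, dtype=float).ravel()
    if v.size != idx.length:
        raise ShapeError(
            f"devectorize_trait: vector length {v.size} != EdgeIndex length "
            f"{idx.length}"
        )
    n = idx.n_nodes
    fc = np.zeros((n, n))
    fc[idx.fc_pairs[:, 0], idx.fc_pairs[:, 1]] = v[idx.fc_slice]
    fc += fc.T
    sc = np.zeros((n, n))
    sc[idx.sc_pairs[:, 0], idx.sc_pairs[:, 1]] = v[idx.sc_slice]
    sc += sc.T
    return fc, sc


@dataclass
class HybridDataset:
    """Profiles x hybrid-edges matrix with per-row metadata."""

    data: np.ndarray  # (P, L_FC + L_SC)
    subjects: list[str]
    conditions: list[str]
    edge_index: EdgeIndex
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != self.edge_index.length:
            raise ShapeError(
                f"HybridDataset: data shape {self.data.shape} does not match "
                f"EdgeIndex length {self.edge_index.length}"
            )
        if len(self.subjects) != len(self.data) or len(self.conditions) != len(
            self.data
        ):
            raise ShapeError("HybridDataset: row metadata length mismatch")
        if not np.isfinite(self.data).all():
            raise ConnectomeError("HybridDataset: non-finite values")
        if not self.node_labels:
            self.node_labels = [f"N{i}" for i in range(self.edge_index.n_nodes)]

    @property
    def n_profiles(self) -> int:
        return self.data.shape[0]

    @property
    def condition_set(self) -> list[str]:
        seen: list[str] = []
        for c in self.conditions:
            if c not in seen:
                seen.append(c)
        return seen

    def to_hdf5(self, path: str | Path) -> Path:
        path = Path(path)
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("fc_pairs", data=self.edge_index.fc_pairs)
            f.create_dataset("sc_pairs", data=self.edge_index.sc_pairs)
            str_dt = h5py.string_dtype()
            f.create_dataset("subjects", data=self.subjects, dtype=str_dt)
            f.create_dataset("conditions", data=self.conditions, dtype=str_dt)
            f.create_dataset("node_labels", data=self.node_labels, dtype=str_dt)
            f.attrs["n_nodes"] = self.edge_index.n_nodes
        return path

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "HybridDataset":
        with h5py.File(path, "r") as f:
            idx = EdgeIndex(
                n_nodes=int(f.attrs["n_nodes"]),
                fc_pairs=f["fc_pairs"][...],
                sc_pairs=f["sc_pairs"][...],
            )
            return cls(
                data=f["data"][...],
                subjects=[s.decode() if isinstance(s, bytes) else s
                          for s in f["subjects"][...]],
                conditions=[s.decode() if isinstance(s, bytes) else s
                            for s in f["conditions"][...]],
                edge_index=idx,
                node_labels=[s.decode() if isinstance(s, bytes) else s
                             for s in f["node_labels"][...]],
            )


def assemble_hybrid(
    profiles: Sequence[tuple[str, str, Connectome, Connectome]],
    idx: EdgeIndex,
) -> HybridDataset:
    """Stack (subject, condition, FC, SC_CORR) profiles into a hybrid matrix.

    Row order follows the input order; any profile failing validation aborts
    the assembly naming the offending subject.
    """
    if len(profiles) == 0:
        raise ConnectomeError("assemble_hybrid: no profiles")
    rows = []
    subjects: list[str] = []
    conditions: list[str] = []
    labels = profiles[0][2].node_labels
    for subject, condition, fc, sc_corr in profiles:
        if fc.modality is not Modality.FC:
            raise ConnectomeError(
                f"assemble_hybrid: subject {subject!r}: expected FC, got "
                f"{fc.modality}"
            )
        if sc_corr.modality is not Modality.SC_CORR:
            raise ConnectomeError(
                f"assemble_hybrid: subject {subject!r}: expected SC_CORR, got "
                f"{sc_corr.modality}"
            )
        try:
            rows.append(vectorize_profile(fc, sc_corr, idx))
        except (ShapeError, ConnectomeError) as exc:
            raise ConnectomeError(
                f"assemble_hybrid: profile ({subject!r}, {condition!r}): {exc}"
            )
        subjects.append(subject)
        conditions.append(condition)
    return HybridDataset(
        data=np.vstack(rows),
        subjects=subjects,
        conditions=conditions,
        edge_index=idx,
        node_labels=labels,
    )
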