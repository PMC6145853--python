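"""Structural-connectome normalization.

Raw structural connectomes (streamline weights) live on a very different
scale than functional connectomes (correlations in [-1, 1]).  Before the two
modalities can be concatenated into a single hybrid profile, SC is brought
into correlation space in two steps:

1. ``log_transform`` compresses the heavy-tailed streamline weights with
   ``w -> log10(1 + w)``, keeping zeros at zero so the sparsity pattern is
   untouched.  For typical streamline counts (up to ~1e5) this maps weights
   into roughly [0, 5].
2. ``structural_correlation`` replaces the weight of each structurally
   connected node pair (i, j) by the Pearson correlation between rows i and j
   of the (log-transformed) SC matrix — a matching-index-style similarity of
   the two nodes' connection profiles, in [-1, 1].

The correlation matrix is dense, so it is restricted to the pairs that are
structurally connected in *every* subject of the population
(``common_edge_mask``, intersection semantics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .connectome import Connectome, ConnectomeError, Modality, ShapeError


def upper_pairs(n: int) -> np.ndarray:
    """Canonical (row-major) list of unordered node pairs i<j, shape (L, 2)."""
    iu = np.triu_indices(n, k=1)
    return np.column_stack(iu)


@dataclass
class EdgeMask:
    """Population-wide indicator over the canonical i<j pair list."""

    n_nodes: int
    indicator: np.ndarray  # bool, length n(n-1)/2, row-major over i<j
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.indicator = np.asarray(self.indicator, dtype=bool)
        expected = self.n_nodes * (self.n_nodes - 1) // 2
        if self.indicator.shape != (expected,):
            raise ShapeError(
                f"edge mask length {self.indicator.shape} != n(n-1)/2 = {expected}"
            )

    @property
    def count(self) -> int:
        return int(self.indicator.sum())

    @property
    def density(self) -> float:
        return self.count / self.indicator.size if self.indicator.size else 0.0

    def pairs(self) -> np.ndarray:
        """Masked node pairs, shape (count, 2), in canonical order."""
        return upper_pairs(self.n_nodes)[self.indicator]

    def to_matrix(self) -> np.ndarray:
        """Symmetric boolean adjacency of the mask."""
        m = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        p = self.pairs()
        m[p[:, 0], p[:, 1]] = True
        m[p[:, 1], p[:, 0]] = True
        return m


def log_transform(sc: Connectome) -> Connectome:
    """Apply ``w -> log10(1 + w)`` to a raw SC.

    Zeros map to zero, so the sparsity pattern (and hence the common-edge
    mask) is unchanged, and the transform is strictly monotone.
    """
    if sc.modality is not Modality.SC_RAW:
        raise ConnectomeError(f"log_transform expects SC_RAW, got {sc.modality}")
    if sc.matrix.min() < 0:
        raise ConnectomeError("log_transform: negative streamline weight")
    return Connectome(
        matrix=np.log10(1.0 + sc.matrix),
        node_labels=sc.node_labels,
        modality=Modality.SC_RAW,
        subject_id=sc.subject_id,
        condition=sc.condition,
    )


def common_edge_mask(scs: Sequence[Connectome]) -> EdgeMask:
    """Pairs with a nonzero structural connection in *all* subjects.

    Intersection semantics: adding a subject can only shrink the mask.
    """
    if len(scs) == 0:
        raise ConnectomeError("common_edge_mask: need at least one SC")
    n = scs[0].n_nodes
    labels = scs[0].node_labels
    pairs = upper_pairs(n)
    indicator = np.ones(len(pairs), dtype=bool)
    provenance = []
    for sc in scs:
        if sc.n_nodes != n:
            raise ShapeError(
                f"common_edge_mask: subject {sc.subject_id!r} has {sc.n_nodes} "
                f"nodes, expected {n}"
            )
        if sc.node_labels != labels:
            raise ConnectomeError(
                f"common_edge_mask: node order mismatch for {sc.subject_id!r}"
            )
        indicator &= sc.matrix[pairs[:, 0], pairs[:, 1]] > 0
        provenance.append(sc.subject_id)
    return EdgeMask(n_nodes=n, indicator=indicator, provenance=provenance)


def structural_correlation(
    sc: Connectome,
    mask: EdgeMask,
    exclude_pair_entries: bool = False,
) -> Connectome:
    """Row-correlation (matching-index style) normalization of an SC.

    For every masked pair (i, j) the output holds the Pearson correlation
    between rows i and j of ``sc.matrix``.  By default the full rows are used
    (including the zero diagonal entries and the mutual entries (i,i), (i,j));
    with ``exclude_pair_entries`` the columns i and j are dropped from both
    rows before correlating, the stricter matching-index convention.

    Unmasked pairs are set to 0 (structurally absent, not observed).  A node
    with a constant row among the masked pairs is a hard error: its
    correlation is undefined.
    """
    if sc.n_nodes != mask.n_nodes:
        raise ShapeError(
            f"structural_correlation: SC has {sc.n_nodes} nodes, mask expects "
            f"{mask.n_nodes}"
        )
    rows = sc.matrix
    pairs = mask.pairs()
    out = np.zeros_like(rows)
    if len(pairs) == 0:
        return Connectome(
            matrix=out,
            node_labels=sc.node_labels,
            modality=Modality.SC_CORR,
            subject_id=sc.subject_id,
            condition=sc.condition,
        )
    if not exclude_pair_entries:
        used = np.unique(pairs)
        constant = used[rows[used].std(axis=1) == 0]
        if constant.size:
            names = [sc.node_labels[i] for i in constant]
            raise ConnectomeError(
                f"structural_correlation: zero-variance row(s) for node(s) "
                f"{names}; correlation undefined"
            )
        corr = np.corrcoef(rows)
        vals = corr[pairs[:, 0], pairs[:, 1]]
    else:
        vals = np.empty(len(pairs))
        n = sc.n_nodes
        for idx, (i, j) in enumerate(pairs):
            keep = np.ones(n, dtype=bool)
            keep[[i, j]] = False
            x, y = rows[i, keep], rows[j, keep]
            if x.std() == 0 or y.std() == 0:
                raise ConnectomeError(
                    f"structural_correlation: zero-variance profile for pair "
                    f"({sc.node_labels[i]}, {sc.node_labels[j]}) after "
                    f"excluding mutual entries"
                )
            vals[idx] = np.corrcoef(x, y)[0, 1]
    vals = np.clip(vals, -1.0, 1.0)
    out[pairs[:, 0], pairs[:, 1]] = vals
    out[pairs[:, 1], pairs[:, 0]] = vals
    return Connectome(
        matrix=out,
        node_labels=sc.node_labels,
        modality=Modality.SC_CORR,
        subject_id=sc.subject_id,
        condition=sc.condition,
    )
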