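"""Mapping hybrid traits onto brain circuits.

A trait vector spans the FC and SC edge blocks.  The edges that matter for
interpretation are the *extreme* ones: per block, values outside the 5th-95th
percentile band.  The joint FC-SC mask keeps node pairs extreme in *both*
blocks simultaneously (elementwise AND of the two binary extreme masks) —
pairs where a task-sensitive functional change co-occurs with an extreme
structural-correlation value.  Nodal strength of the mask (number of masked
edges incident to each node) ranks regions by their involvement in the
circuit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .hybrid import EdgeIndex
from .connectome import ShapeError

#: percentiles use numpy's linear-interpolation convention, inclusive bounds
PERCENTILE_CONVENTION = "linear"


def percentile_mask(
    values: np.ndarray, lo: float = 5.0, hi: float = 95.0
) -> np.ndarray:
    """Binary mask of values strictly outside the [lo, hi] percentile band.

    Percentiles are computed with linear interpolation; an entry is selected
    iff value < P_lo or value > P_hi, so for continuous data the expected
    selected fraction is (lo + 100 - hi)/100.  A constant vector selects
    nothing (with a warning).
    """
    values = np.asarray(values, dtype=float)
    if not (0 <= lo <= hi <= 100):
        raise ValueError("percentile_mask: need 0 <= lo <= hi <= 100")
    finite = np.isfinite(values)
    if finite.sum() < 20:
        raise ValueError(
            f"percentile_mask: need >= 20 finite values, got {int(finite.sum())}"
        )
    if values[finite].min() == values[finite].max():
        warnings.warn("percentile_mask: all values equal; empty mask")
        return np.zeros_like(values, dtype=bool)
    p_lo, p_hi = np.percentile(values[finite], [lo, hi], method="linear")
    mask = np.zeros_like(values, dtype=bool)
    mask[finite] = (values[finite] < p_lo) | (values[finite] > p_hi)
    return mask


@dataclass
class JointMask:
    """Joint FC-SC extreme-value mask of one hybrid trait."""

    matrix: np.ndarray          # (n, n) bool, symmetric: joint mask
    fc_matrix: np.ndarray       # (n, n) bool: FC-extreme pairs
    sc_matrix: np.ndarray       # (n, n) bool: SC-extreme pairs
    lo: float
    hi: float
    fc_count: int               # number of FC-extreme pairs
    sc_count: int
    joint_count: int
    convention: str = PERCENTILE_CONVENTION


def _scatter(pairs: np.ndarray, flags: np.ndarray, n: int) -> np.ndarray:
    m = np.zeros((n, n), dtype=bool)
    sel = pairs[flags]
    m[sel[:, 0], sel[:, 1]] = True
    m[sel[:, 1], sel[:, 0]] = True
    return m


def joint_fc_sc_mask(
    trait_vector: np.ndarray,
    idx: EdgeIndex,
    lo: float = 5.0,
    hi: float = 95.0,
) -> JointMask:
    """Extreme-value masks per block and their joint (AND) mask.

    Percentiles are taken per block: over all FC edges for the FC half and
    over the masked SC edges only for the SC half (unmasked SC pairs are
    structurally absent, not zero observations, so they can never be joint).
    """
    v = np.asarray(trait_vector, dtype=float).ravel()
    if v.size != idx.length:
        raise ShapeError(
            f"joint_fc_sc_mask: trait length {v.size} != EdgeIndex length "
            f"{idx.length}"
        )
    fc_flags = percentile_mask(v[idx.fc_slice], lo, hi)
    sc_flags = percentile_mask(v[idx.sc_slice], lo, hi)
    n = idx.n_nodes
    fc_m = _scatter(idx.fc_pairs, fc_flags, n)
    sc_m = _scatter(idx.sc_pairs, sc_flags, n)
    joint = fc_m & sc_m
    return JointMask(
        matrix=joint,
        fc_matrix=fc_m,
        sc_matrix=sc_m,
        lo=float(lo),
        hi=float(hi),
        fc_count=int(fc_flags.sum()),
        sc_count=int(sc_flags.sum()),
        joint_count=int(joint.sum()) // 2,
    )


def nodal_strength(mask: JointMask | np.ndarray) -> np.ndarray:
    """Number of masked pairs incident to each node.

    Satisfies the handshake identity: strengths sum to twice the number of
    masked pairs.
    """
    m = mask.matrix if isinstance(mask, JointMask) else np.asarray(mask, bool)
    return m.sum(axis=1).astype(int)
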