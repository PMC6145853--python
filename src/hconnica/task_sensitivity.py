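"""Task sensitivity of hybrid-trait weights via intraclass correlation.

A trait is task-sensitive when the per-profile weights separate the task
conditions: profiles performing the same task agree more than profiles
performing different tasks.  This is scored with the one-way random-effects
intraclass correlation (ICC(1,1), Shrout-Fleiss case 1 analog, conditions as
groups):

    ICC = (MSB - MSW) / (MSB + (k0 - 1) * MSW)

where MSB/MSW are the between/within-group mean squares of the one-way ANOVA
and k0 is the mean group size corrected for imbalance,
k0 = (N - sum(k_i^2)/N) / (g - 1), which reduces to the common group size k
for balanced designs.  ICC is invariant under adding a constant to all
weights and under global positive rescaling, and is at most 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .decomposition import RobustTrait


class SensitivityError(ValueError):
    pass


@dataclass
class ICCResult:
    icc: float
    msb: float
    msw: float
    k0: float
    group_sizes: dict[str, int]


@dataclass
class SensitivityReport:
    """Per-trait task-sensitivity summary."""

    trait_id: int
    icc: float
    msb: float
    msw: float
    sensitive: bool
    group_sizes: dict[str, int]
    condition_means: dict[str, float]
    frequency: float = float("nan")


def icc_oneway(
    values: Sequence[float], groups: Sequence[str]
) -> ICCResult:
    """One-way random-effects ICC(1,1) of values grouped by condition.

    Missing (NaN) values are dropped.  Requires at least two groups with at
    least two values each; all-identical data is an explicit error (the ICC
    is undefined when MSB = MSW = 0).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    if values.shape != groups.shape:
        raise SensitivityError("icc_oneway: values and groups length mismatch")
    keep = np.isfinite(values)
    values, groups = values[keep], groups[keep]
    labels = list(dict.fromkeys(groups.tolist()))
    if len(labels) < 2:
        raise SensitivityError("icc_oneway: need >= 2 groups")
    sizes, ssb, ssw = {}, 0.0, 0.0
    grand = values.mean()
    for lab in labels:
        x = values[groups == lab]
        if len(x) < 2:
            raise SensitivityError(
                f"icc_oneway: group {lab!r} has < 2 values after dropping "
                f"missing weights"
            )
        sizes[lab] = len(x)
        ssb += len(x) * (x.mean() - grand) ** 2
        ssw += ((x - x.mean()) ** 2).sum()
    N, g = len(values), len(labels)
    msb = ssb / (g - 1)
    msw = ssw / (N - g)
    if msb == 0.0 and msw == 0.0:
        raise SensitivityError(
            "icc_oneway: all values identical; ICC undefined"
        )
    k0 = (N - sum(k * k for k in sizes.values()) / N) / (g - 1)
    icc = (msb - msw) / (msb + (k0 - 1) * msw)
    return ICCResult(icc=float(icc), msb=float(msb), msw=float(msw),
                     k0=float(k0), group_sizes=sizes)


def classify_task_sensitive(
    traits: Sequence[RobustTrait],
    conditions: Sequence[str],
    icc_threshold: float = 0.5,
) -> list[SensitivityReport]:
    """Score each robust trait's weights for condition separability.

    Profiles whose weight is missing (never sampled in a member run) are
    dropped.  Reports are sorted by ICC, descending; ``sensitive`` flags
    ICC >= ``icc_threshold``.
    """
    conditions = np.asarray(conditions, dtype=object)
    reports = []
    for tid, trait in enumerate(traits):
        w = trait.weights
        if w.shape != conditions.shape:
            raise SensitivityError(
                f"classify_task_sensitive: trait {tid} has {w.shape} weights "
                f"for {conditions.shape} profiles"
            )
        res = icc_oneway(w, conditions)
        cond_means = {}
        for lab in res.group_sizes:
            sel = (conditions == lab) & np.isfinite(w)
            cond_means[lab] = float(w[sel].mean())
        reports.append(
            SensitivityReport(
                trait_id=tid,
                icc=res.icc,
                msb=res.msb,
                msw=res.msw,
                sensitive=bool(res.icc >= icc_threshold),
                group_sizes=res.group_sizes,
                condition_means=cond_means,
                frequency=trait.frequency,
            )
        )
    reports.sort(key=lambda r: -r.icc)
    return reports
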