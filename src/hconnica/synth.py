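"""Synthetic cohorts with planted hybrid traits.

The generator emulates the data structure the decomposition expects — a
cross-sectional cohort of profiles (one subject per condition slot, e.g.
8 conditions x 10 subjects = 80 profiles) sharing K latent hybrid traits —
at two levels:

* **Level A** (``generate_hybrid_population``): the hybrid matrix is built
  directly from the ICA generative model, ``row_p = sum_k a_pk t_k + noise``.
  Planted trait vectors are RSN-block structured (constant within designated
  within-/between-network blocks, positive within the home network, negative
  between, plus jitter), mutually orthogonalized per block, and scaled to a
  common RMS amplitude (the *trait scale*).  Weights of task-sensitive traits
  have condition-dependent means (spread ``condition_shift`` x ``weight_sd``
  across conditions); insensitive traits share one mean.  Edge noise is
  i.i.d. normal with sd = ``noise_sd_factor`` x trait scale.
* **Level B** (``generate_raw_connectomes``): raw inputs for the end-to-end
  pipeline.  FCs de-vectorize the FC half of the level-A rows.  Raw SCs share
  a stochastic-block core topology (every core edge present in all subjects,
  so the common-edge mask is the core), with per-subject extra edges,
  log-normal edge weights, and — crucially — log-weight modulation of each
  trait's structural block by that subject's trait weight, which couples the
  structural correlations to the planted traits.  Because the
  row-correlation transform is not invertible, level B guarantees only
  qualitative trait recovery.

Setting ``randomize_core_swaps > 0`` rebuilds the cohort on a
degree-preserved randomization of the core topology (destroying the FC-SC
block alignment while leaving the FC matrices bit-identical), the control
condition for the structural-randomization analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .connectome import (
    Connectome,
    Modality,
    NodePartition,
    write_connectome,
    write_node_partition,
)
from .decomposition import RobustTrait
from .hybrid import EdgeIndex, HybridDataset, devectorize_trait
from .null_models import degree_preserving_randomize
from .sc_transform import EdgeMask, upper_pairs

#: condition labels mirroring a 7-task + rest protocol
DEFAULT_CONDITIONS = (
    "REST", "EMOTION", "GAMBLING", "LANGUAGE",
    "MOTOR", "RELATIONAL", "SOCIAL", "WM",
)
DEFAULT_RSNS = ("VIS", "SM", "DA", "VA", "L", "FP", "DMN", "SUBC")


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic cohort.

    Defaults produce the standard study conditions: 80 profiles (8 conditions
    x 10 subjects), 5 planted traits of which 2 task-sensitive, edge noise sd
    equal to 0.2 x the trait scale, and a block-model SC whose common core
    covers roughly a fifth of all node pairs.
    """

    n_nodes: int = 64
    n_rsn: int = 8
    n_conditions: int = 8
    n_subjects_per_condition: int = 10
    n_traits: int = 5
    n_task_sensitive: int = 2
    trait_scale: float = 0.1        # RMS amplitude of each trait-vector block
    trait_jitter: float = 0.25      # relative jitter of block values
    trait_background: float = 0.1   # off-support entries, relative to block value
    weight_sd: float = 0.12         # within-condition sd of trait weights
    condition_shift: float = 2.0    # condition-mean spread, in units of weight_sd
    noise_sd_factor: float = 0.2    # edge noise sd = factor x trait_scale
    sc_within_density: float = 0.6  # core SBM density inside an RSN
    sc_between_density: float = 0.12
    sc_extra_density: float = 0.03  # per-subject non-core edges
    sc_log_weight_mean: float = 2.0  # log10 streamline-weight scale
    sc_log_weight_sd: float = 0.7
    sc_subject_jitter: float = 0.15  # per-subject log10 weight jitter sd
    sc_coupling: float = 0.5        # trait-weight modulation of log-SC blocks
    master_seed: int = 0

    def __post_init__(self) -> None:
        P = self.n_conditions * self.n_subjects_per_condition
        if self.n_traits > P:
            raise ValueError("n_traits must not exceed the number of profiles")
        if self.n_task_sensitive > self.n_traits:
            raise ValueError("n_task_sensitive must not exceed n_traits")
        if self.noise_sd_factor < 0:
            raise ValueError("noise_sd_factor must be >= 0")
        if self.n_rsn > self.n_nodes:
            raise ValueError("more RSNs than nodes")

    @property
    def n_profiles(self) -> int:
        return self.n_conditions * self.n_subjects_per_condition

    @property
    def condition_labels(self) -> list[str]:
        if self.n_conditions <= len(DEFAULT_CONDITIONS):
            return list(DEFAULT_CONDITIONS[: self.n_conditions])
        return [f"COND{i}" for i in range(self.n_conditions)]

    @property
    def rsn_labels(self) -> list[str]:
        if self.n_rsn <= len(DEFAULT_RSNS):
            return list(DEFAULT_RSNS[: self.n_rsn])
        return [f"RSN{i}" for i in range(self.n_rsn)]


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort."""

    traits: np.ndarray              # (K, L) planted hybrid trait vectors
    weights: np.ndarray             # (P, K) planted weights
    subjects: list[str]
    conditions: list[str]
    task_sensitive: np.ndarray      # (K,) bool
    condition_means: pd.DataFrame   # K x conditions
    edge_index: EdgeIndex
    seed: int


@dataclass
class SyntheticCohort:
    """A full level-B cohort: raw connectomes plus ground truth."""

    fcs: list[Connectome]           # one per profile
    scs: list[Connectome]           # one per profile (SC of that subject)
    subjects: list[str]
    conditions: list[str]
    partition: NodePartition
    core_mask: EdgeMask
    truth: SyntheticTruth


def _rsn_assignment(spec: SyntheticSpec) -> np.ndarray:
    """Node -> RSN id, contiguous nearly-equal blocks."""
    return np.array(
        [min(i * spec.n_rsn // spec.n_nodes, spec.n_rsn - 1)
         for i in range(spec.n_nodes)]
    )


def _core_topology(spec: SyntheticSpec, rsn: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Boolean indicator over canonical i<j pairs: the shared SC core."""
    pairs = upper_pairs(spec.n_nodes)
    same = rsn[pairs[:, 0]] == rsn[pairs[:, 1]]
    p = np.where(same, spec.sc_within_density, spec.sc_between_density)
    core = rng.random(len(pairs)) < p
    # every node needs at least two core edges (row-correlation needs
    # non-constant rows and the swap null needs non-isolated nodes)
    deg = np.zeros(spec.n_nodes, dtype=int)
    np.add.at(deg, pairs[core, 0], 1)
    np.add.at(deg, pairs[core, 1], 1)
    for node in range(spec.n_nodes):
        need = 2 - deg[node]
        if need <= 0:
            continue
        incident = np.flatnonzero(
            (pairs[:, 0] == node) | (pairs[:, 1] == node)
        )
        candidates = incident[~core[incident]]
        add = rng.choice(candidates, size=need, replace=False)
        core[add] = True
        for e in add:
            deg[pairs[e, 0]] += 1
            deg[pairs[e, 1]] += 1
    return core


def _block_pair_selector(pairs: np.ndarray, rsn: np.ndarray,
                         a: int, b: int) -> np.ndarray:
    ra, rb = rsn[pairs[:, 0]], rsn[pairs[:, 1]]
    return ((ra == a) & (rb == b)) | ((ra == b) & (rb == a))


def _orthogonalize_block(T: np.ndarray) -> np.ndarray:
    """Gram-Schmidt the rows of T (in place order), no normalization."""
    out = T.copy()
    for k in range(1, out.shape[0]):
        for j in range(k):
            denom = out[j] @ out[j]
            if denom > 0:
                out[k] -= (out[k] @ out[j]) / denom * out[j]
    return out


def _plant_traits(
    spec: SyntheticSpec,
    idx: EdgeIndex,
    rsn: np.ndarray,
    rng_fc: np.random.Generator,
    rng_sc: np.random.Generator,
) -> tuple[np.ndarray, list[dict]]:
    """Build K orthogonalized, block-structured hybrid trait vectors.

    FC and SC blocks are orthogonalized and scaled separately (each to RMS =
    ``trait_scale``) so the FC half of every trait is independent of the SC
    topology.
    """
    K = spec.n_traits
    homes = [k % spec.n_rsn for k in range(K)]
    partners = []
    for k in range(K):
        others = [r for r in range(spec.n_rsn) if r != homes[k]]
        partners.append(int(rng_fc.choice(others)))

    def block_vector(pairs: np.ndarray, rng: np.random.Generator,
                     home: int, partner: int) -> np.ndarray:
        v = rng.normal(0.0, spec.trait_background, len(pairs))
        within = _block_pair_selector(pairs, rsn, home, home)
        between = _block_pair_selector(pairs, rsn, home, partner)
        v[within] = 1.0 + rng.normal(0.0, spec.trait_jitter, within.sum())
        v[between] = -1.0 + rng.normal(0.0, spec.trait_jitter, between.sum())
        return v

    T_fc = np.vstack([
        block_vector(idx.fc_pairs, rng_fc, homes[k], partners[k])
        for k in range(K)
    ])
    T_sc = np.vstack([
        block_vector(idx.sc_pairs, rng_sc, homes[k], partners[k])
        for k in range(K)
    ])
    T_fc = _orthogonalize_block(T_fc)
    T_sc = _orthogonalize_block(T_sc)

    def rescale(T: np.ndarray) -> np.ndarray:
        rms = np.sqrt((T ** 2).mean(axis=1, keepdims=True))
        rms[rms == 0] = 1.0
        return T / rms * spec.trait_scale

    T = np.hstack([rescale(T_fc), rescale(T_sc)])
    info = [
        {"home": spec.rsn_labels[homes[k]],
         "partner": spec.rsn_labels[partners[k]]}
        for k in range(K)
    ]
    return T, info


def _plant_weights(
    spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, list[str], list[str]]:
    conds = spec.condition_labels
    subjects = [f"S{i:03d}" for i in range(spec.n_profiles)]
    conditions = [conds[i // spec.n_subjects_per_condition]
                  for i in range(spec.n_profiles)]
    K, C = spec.n_traits, spec.n_conditions
    sensitive = np.zeros(K, dtype=bool)
    sensitive[: spec.n_task_sensitive] = True
    mu = np.zeros((K, C))
    base_profile = np.linspace(-1.0, 1.0, C)
    for k in range(K):
        if sensitive[k]:
            mu[k] = (spec.condition_shift * spec.weight_sd
                     * rng.permutation(base_profile))
    A = np.empty((spec.n_profiles, K))
    cond_of = np.array([conds.index(c) for c in conditions])
    for k in range(K):
        A[:, k] = rng.normal(mu[k, cond_of], spec.weight_sd)
    means = pd.DataFrame(mu, columns=conds,
                         index=[f"trait{k}" for k in range(K)])
    return A, sensitive, means, subjects, conditions


def _seed_streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("topology", "traits_fc", "traits_sc", "weights", "noise",
             "sc_weights", "randomize")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def generate_hybrid_population(
    spec: SyntheticSpec, seed: int | None = None
) -> tuple[HybridDataset, SyntheticTruth]:
    """Level-A cohort: hybrid matrix drawn from the ICA generative model.

    ``row_p = sum_k a_pk t_k + eps`` with i.i.d. normal edge noise; the FC
    block is clipped to [-1, 1] (with a warning if clipping touches more than
    1% of entries).  Deterministic given the seed.
    """
    if seed is None:
        seed = spec.master_seed
    streams = _seed_streams(seed)
    rsn = _rsn_assignment(spec)
    core = _core_topology(spec, rsn, streams["topology"])
    mask = EdgeMask(n_nodes=spec.n_nodes, indicator=core,
                    provenance=["synthetic-core"])
    idx = EdgeIndex.from_mask(mask)
    T, _ = _plant_traits(spec, idx, rsn, streams["traits_fc"],
                         streams["traits_sc"])
    A, sensitive, means, subjects, conditions = _plant_weights(
        spec, streams["weights"]
    )
    noise_sd = spec.noise_sd_factor * spec.trait_scale
    data = A @ T
    if noise_sd > 0:
        data = data + streams["noise"].normal(0.0, noise_sd, data.shape)
    fc_block = data[:, idx.fc_slice]
    n_clip = int((np.abs(fc_block) > 1.0).sum())
    if n_clip > 0.01 * fc_block.size:
        warnings.warn(
            f"generate_hybrid_population: clipping affects "
            f"{n_clip / fc_block.size:.2%} of FC entries; trait scale may be "
            f"too large"
        )
    data[:, idx.fc_slice] = np.clip(fc_block, -1.0, 1.0)
    data[:, idx.sc_slice] = np.clip(data[:, idx.sc_slice], -1.0, 1.0)
    hybrid = HybridDataset(
        data=data,
        subjects=subjects,
        conditions=conditions,
        edge_index=idx,
        node_labels=[f"N{i:03d}" for i in range(spec.n_nodes)],
    )
    truth = SyntheticTruth(
        traits=T, weights=A, subjects=subjects, conditions=conditions,
        task_sensitive=sensitive, condition_means=means, edge_index=idx,
        seed=int(seed),
    )
    return hybrid, truth


def generate_raw_connectomes(
    spec: SyntheticSpec,
    seed: int | None = None,
    out_dir: str | Path | None = None,
    randomize_core_swaps: int = 0,
) -> SyntheticCohort:
    """Level-B cohort: raw FC/SC matrices, partition, optional file output.

    With ``randomize_core_swaps > 0`` the shared core topology is rewired by
    that many degree-preserving swaps before weights and trait coupling are
    laid on it; the FC matrices are unchanged, so a run with and a run
    without randomization form a matched pair.
    """
    if seed is None:
        seed = spec.master_seed
    streams = _seed_streams(seed)
    rsn = _rsn_assignment(spec)
    core = _core_topology(spec, rsn, streams["topology"])
    n = spec.n_nodes
    pairs = upper_pairs(n)
    node_labels = [f"N{i:03d}" for i in range(n)]

    if randomize_core_swaps > 0:
        adj = np.zeros((n, n))
        sel = pairs[core]
        adj[sel[:, 0], sel[:, 1]] = 1.0
        adj[sel[:, 1], sel[:, 0]] = 1.0
        binary = Connectome(matrix=adj, node_labels=node_labels,
                            modality=Modality.SC_RAW, subject_id="core")
        rand_seed = int(
            streams["randomize"].integers(0, 2**31 - 1)
        )
        null = degree_preserving_randomize(
            binary, randomize_core_swaps, seed=rand_seed
        )
        core = null.connectome.matrix[pairs[:, 0], pairs[:, 1]] > 0

    mask = EdgeMask(n_nodes=n, indicator=core, provenance=["synthetic-core"])
    idx = EdgeIndex.from_mask(mask)
    T, _ = _plant_traits(spec, idx, rsn, streams["traits_fc"],
                         streams["traits_sc"])
    A, sensitive, means, subjects, conditions = _plant_weights(
        spec, streams["weights"]
    )

    # --- functional connectomes: de-vectorized FC half of the hybrid rows
    noise_sd = spec.noise_sd_factor * spec.trait_scale
    fc_rows = A @ T[:, idx.fc_slice]
    if noise_sd > 0:
        fc_rows = fc_rows + streams["noise"].normal(0.0, noise_sd, fc_rows.shape)
    fc_rows = np.clip(fc_rows, -1.0, 1.0)
    fcs = []
    for p in range(spec.n_profiles):
        m = np.zeros((n, n))
        m[idx.fc_pairs[:, 0], idx.fc_pairs[:, 1]] = fc_rows[p]
        m += m.T
        fcs.append(Connectome(
            matrix=m, node_labels=node_labels, modality=Modality.FC,
            subject_id=subjects[p], condition=conditions[p],
        ))

    # --- structural connectomes: shared core, log-normal weights, trait
    # coupling in log10 space on each trait's structural block
    rng_w = streams["sc_weights"]
    base_log = np.clip(
        rng_w.normal(spec.sc_log_weight_mean, spec.sc_log_weight_sd,
                     mask.count),
        0.2, 4.8,
    )
    # sign pattern of each trait on the core pairs (+1 within home RSN,
    # -1 between home and partner): reuse the planted SC half's sign
    patterns = np.sign(T[:, idx.sc_slice])
    # only the block structure should couple, not the background jitter
    strong = np.abs(T[:, idx.sc_slice]) > 2.0 * np.abs(
        T[:, idx.sc_slice]
    ).mean(axis=1, keepdims=True)
    patterns = patterns * strong
    core_pairs = idx.sc_pairs
    extra_candidates = np.flatnonzero(~core)
    scs = []
    for p in range(spec.n_profiles):
        log_w = base_log + rng_w.normal(0.0, spec.sc_subject_jitter,
                                        mask.count)
        log_w = log_w + spec.sc_coupling * (A[p] @ patterns)
        log_w = np.clip(log_w, 0.05, 5.0)
        m = np.zeros((n, n))
        m[core_pairs[:, 0], core_pairs[:, 1]] = 10.0 ** log_w - 1.0
        if spec.sc_extra_density > 0 and extra_candidates.size:
            n_extra = rng_w.binomial(extra_candidates.size,
                                     spec.sc_extra_density)
            chosen = rng_w.choice(extra_candidates, size=n_extra,
                                  replace=False)
            ep = pairs[chosen]
            m[ep[:, 0], ep[:, 1]] = 10.0 ** rng_w.uniform(
                0.05, 1.0, n_extra
            ) - 1.0
        m = m + m.T
        scs.append(Connectome(
            matrix=m, node_labels=node_labels, modality=Modality.SC_RAW,
            subject_id=subjects[p], condition=conditions[p],
        ))

    partition = NodePartition(
        node_labels=node_labels,
        rsn=[spec.rsn_labels[r] for r in rsn],
    )
    truth = SyntheticTruth(
        traits=T, weights=A, subjects=subjects, conditions=conditions,
        task_sensitive=sensitive, condition_means=means, edge_index=idx,
        seed=int(seed),
    )
    cohort = SyntheticCohort(
        fcs=fcs, scs=scs, subjects=subjects, conditions=conditions,
        partition=partition, core_mask=mask, truth=truth,
    )
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _write_cohort(cohort: SyntheticCohort, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for p, (subject, condition) in enumerate(
        zip(cohort.subjects, cohort.conditions)
    ):
        fc_name = f"fc_{subject}_{condition}.tsv"
        sc_name = f"sc_{subject}.tsv"
        write_connectome(cohort.fcs[p], out_dir / fc_name)
        write_connectome(cohort.scs[p], out_dir / sc_name)
        rows.append({"subject_id": subject, "condition": condition,
                     "fc_path": fc_name, "sc_path": sc_name})
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    write_node_partition(cohort.partition, out_dir / "partition.csv")


def evaluate_recovery(
    truth: SyntheticTruth,
    traits: list[RobustTrait],
    block: str = "both",
) -> pd.DataFrame:
    """Match recovered traits to planted ones and score the recovery.

    One-to-one assignment maximizing |Pearson r| between trait vectors
    (Hungarian algorithm); per matched pair the table reports the trait |r|
    (over the requested block: "both", "fc" or "sc") and the weight |r| over
    co-observed profiles.  Sign flips are immaterial.  Planted traits left
    unmatched (fewer recovered than planted) get NaN rows.
    """
    idx = truth.edge_index
    if block == "both":
        sl = slice(0, idx.length)
    elif block == "fc":
        sl = idx.fc_slice
    elif block == "sc":
        sl = idx.sc_slice
    else:
        raise ValueError(f"unknown block {block!r}")
    K = truth.traits.shape[0]
    rows = []
    if traits:
        R = np.vstack([t.vector[sl] for t in traits])
        if R.shape[1] != truth.traits[:, sl].shape[1]:
            raise ValueError(
                "evaluate_recovery: recovered traits live in a different "
                "hybrid-edge space than the truth"
            )
        P_t = truth.traits[:, sl]
        cross = np.zeros((K, len(traits)))
        for i in range(K):
            for j in range(len(traits)):
                cross[i, j] = abs(float(np.corrcoef(P_t[i], R[j])[0, 1]))
        ri, cj = linear_sum_assignment(-cross)
        matched = dict(zip(ri.tolist(), cj.tolist()))
    else:
        matched = {}
    for k in range(K):
        if k in matched:
            j = matched[k]
            trait_r = float(cross[k, j])
            w = traits[j].weights
            ok = np.isfinite(w)
            if ok.sum() >= 3 and np.std(truth.weights[ok, k]) > 0 \
                    and np.std(w[ok]) > 0:
                weight_r = abs(float(
                    np.corrcoef(truth.weights[ok, k], w[ok])[0, 1]
                ))
            else:
                weight_r = float("nan")
            rows.append({
                "planted": k, "recovered": j, "trait_abs_r": trait_r,
                "weight_abs_r": weight_r,
                "task_sensitive": bool(truth.task_sensitive[k]),
                "frequency": traits[j].frequency,
            })
        else:
            rows.append({
                "planted": k, "recovered": -1, "trait_abs_r": float("nan"),
                "weight_abs_r": float("nan"),
                "task_sensitive": bool(truth.task_sensitive[k]),
                "frequency": float("nan"),
            })
    return pd.DataFrame(rows)
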