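"""PCA denoising, multi-run FastICA, and robustness clustering.

The decomposition works on the hybrid matrix (profiles x hybrid edges):

1. ``pca_denoise`` reconstructs the matrix from the smallest set of leading
   principal components explaining a target fraction (default 90%) of the
   variance — a denoising step that keeps the matrix on its original scale.
2. For each of ``n_runs`` bootstrap runs, a balanced cohort of distinct
   subjects (``n_per_condition`` per condition) is sampled and FastICA is
   applied to the transposed subset, yielding M independent *hybrid traits*
   (unit-norm vectors over hybrid-edge space) and per-profile mixing
   *weights*.
3. ``cluster_robust_traits`` greedily groups components across runs by
   absolute Pearson correlation; a cluster appearing (|r| >= ``r_thresh``)
   in at least a fraction ``freq_thresh`` of runs is a *robust trait*, its
   vector the mean of its sign-aligned members and its weights the
   per-profile mean over the member runs that sampled that profile.

Model order M (number of ICA components) has no gold standard; the heuristic
``select_model_order`` scans a range of M and keeps the one maximizing the
number of robust, task-sensitive traits (lexicographic tie-break on mean ICC,
then smaller M).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching
from sklearn.decomposition import PCA, FastICA
from sklearn.exceptions import ConvergenceWarning

from .hybrid import HybridDataset


class DecompositionError(ValueError):
    pass


class InsufficientSubjectsError(DecompositionError):
    pass


@dataclass
class DecompositionConfig:
    """Tunable parameters of the hybrid decomposition.

    Defaults follow the reference workflow: 90% PCA variance, M = 10
    components, 100 bootstrap ICA runs, robustness thresholds r >= 0.5 in
    >= 50% of runs, cohorts of 10 subjects per condition, tanh (log-cosh)
    contrast with symmetric decorrelation.
    """

    n_components: int = 10
    variance_fraction: float = 0.90
    n_runs: int = 100
    r_thresh: float = 0.5
    freq_thresh: float = 0.50
    n_per_condition: int = 10
    fun: str = "logcosh"
    max_iter: int = 500
    tol: float = 1e-4
    discard_nonconverged: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.variance_fraction <= 1):
            raise DecompositionError("variance_fraction must be in (0, 1]")
        if self.n_components < 2:
            raise DecompositionError("n_components must be >= 2")
        for name in ("r_thresh", "freq_thresh"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise DecompositionError(f"{name} must be in (0, 1]")


@dataclass
class RunResult:
    """One FastICA run on one bootstrap cohort."""

    run_id: int
    profile_indices: np.ndarray      # global row ids of the sampled cohort
    components: np.ndarray           # (M, L) unit-norm trait vectors
    weights: np.ndarray              # (P_run, M) mixing weights
    converged: bool
    seed: int


@dataclass
class RobustTrait:
    """A cross-run-stable hybrid trait with per-profile weights.

    ``weights[p]`` is the mean (sign-aligned) weight over member runs that
    sampled profile p, NaN if p was never sampled in a member run;
    ``counts[p]`` is the number of contributing runs.
    """

    vector: np.ndarray               # (L,)
    weights: np.ndarray              # (P,) with NaN for never-sampled
    counts: np.ndarray               # (P,) int
    frequency: float                 # fraction of converged runs
    members: list[tuple[int, int, float, int]] = field(default_factory=list)
    # members: (run_id, component_id, r to seed, sign)


def pca_denoise(
    data: np.ndarray | HybridDataset, variance_fraction: float = 0.90
) -> tuple[np.ndarray, int, np.ndarray]:
    """Rank-k PCA reconstruction at a cumulative explained-variance target.

    Columns are mean-centered for the PCA and the means are re-added to the
    reconstruction, so the output keeps the original scale.  Returns the
    reconstruction, the number of retained components k, and the cumulative
    explained-variance curve.
    """
    if not (0 < variance_fraction <= 1):
        raise DecompositionError("variance_fraction must be in (0, 1]")
    X = data.data if isinstance(data, HybridDataset) else np.asarray(data, float)
    if X.shape[0] < 2:
        raise DecompositionError("pca_denoise: need at least 2 profiles")
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
    k = min(k, len(cum))
    recon = scores[:, :k] @ pca.components_[:k] + pca.mean_
    return recon, k, cum


def sample_run_cohort(
    subjects: Sequence[str],
    conditions: Sequence[str],
    n_per_condition: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample a balanced cohort of distinct subjects.

    Chooses exactly ``n_per_condition`` profile rows per condition such that
    every selected subject appears once in the whole cohort.  Randomized
    greedy assignment with a bipartite-matching fallback guarantees a valid
    cohort is found whenever one exists.  Returns global row indices sorted
    ascending (row order of the hybrid matrix is preserved).
    """
    subjects = np.asarray(subjects, dtype=object)
    conditions = np.asarray(conditions, dtype=object)
    cond_set = list(dict.fromkeys(conditions.tolist()))
    n_cond = len(cond_set)
    uniq_subjects = list(dict.fromkeys(subjects.tolist()))
    if len(uniq_subjects) < n_per_condition * n_cond:
        raise InsufficientSubjectsError(
            f"need {n_per_condition * n_cond} distinct subjects "
            f"({n_per_condition} x {n_cond} conditions), have {len(uniq_subjects)}"
        )

    rows_by_cond: dict[str, np.ndarray] = {
        c: np.flatnonzero(conditions == c) for c in cond_set
    }

    def greedy() -> np.ndarray | None:
        used: set[str] = set()
        chosen: list[int] = []
        for c in rng.permutation(n_cond):
            cond = cond_set[c]
            rows = rows_by_cond[cond]
            rows = rows[rng.permutation(len(rows))]
            picked = 0
            for r in rows:
                if subjects[r] not in used:
                    used.add(subjects[r])
                    chosen.append(int(r))
                    picked += 1
                    if picked == n_per_condition:
                        break
            if picked < n_per_condition:
                return None
        return np.array(sorted(chosen))

    for _ in range(50):
        result = greedy()
        if result is not None:
            return result

    # Exact fallback: subjects x (condition slots) bipartite matching.
    subj_order = [uniq_subjects[i] for i in rng.permutation(len(uniq_subjects))]
    subj_idx = {s: i for i, s in enumerate(subj_order)}
    slot_of = []  # slot -> condition
    for c in cond_set:
        slot_of.extend([c] * n_per_condition)
    cond_slot0 = {c: cond_set.index(c) * n_per_condition for c in cond_set}
    rows_i, cols_j = [], []
    for c in cond_set:
        for r in rows_by_cond[c]:
            for k in range(n_per_condition):
                rows_i.append(subj_idx[subjects[r]])
                cols_j.append(cond_slot0[c] + k)
    graph = csr_matrix(
        (np.ones(len(rows_i)), (rows_i, cols_j)),
        shape=(len(subj_order), len(slot_of)),
    )
    match = maximum_bipartite_matching(graph, perm_type="column")
    # match[subject] = slot or -1
    chosen = []
    used_slots = match[match >= 0]
    if len(used_slots) < len(slot_of):
        raise InsufficientSubjectsError(
            "no balanced cohort of distinct subjects exists for this manifest"
        )
    row_lookup = {
        (subjects[r], conditions[r]): int(r) for r in range(len(subjects))
    }
    for si, slot in enumerate(match):
        if slot >= 0:
            chosen.append(row_lookup[(subj_order[si], slot_of[slot])])
    return np.array(sorted(chosen))


def _effective_rank(X: np.ndarray) -> int:
    s = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
    if s.size == 0:
        return 0
    tol = s.max() * max(X.shape) * np.finfo(float).eps
    return int((s > tol).sum())


def run_ica(
    data: np.ndarray,
    n_components: int,
    seed: int,
    fun: str = "logcosh",
    max_iter: int = 500,
    tol: float = 1e-6,
    profile_indices: np.ndarray | None = None,
    run_id: int = 0,
) -> RunResult:
    """FastICA on a (cohort x hybrid edges) matrix.

    The matrix is decomposed as ``X ~ weights @ components`` (plus per-profile
    offsets): FastICA is fitted on the transpose so that sources live in
    hybrid-edge space.  Components are unit-normalized, the scale carried by
    the weights; fixed-point iteration with symmetric ("parallel")
    decorrelation and the configured contrast function.  Deterministic given
    the seed.  Non-convergence after ``max_iter`` is flagged (the run is then
    discarded from clustering), not raised.
    """
    X = np.asarray(data, dtype=float)
    P, L = X.shape
    rank = _effective_rank(X)
    if n_components > rank:
        raise DecompositionError(
            f"run_ica: M = {n_components} exceeds data rank {rank}"
        )
    ica = FastICA(
        n_components=n_components,
        algorithm="parallel",
        fun=fun,
        max_iter=max_iter,
        tol=tol,
        whiten="unit-variance",
        random_state=int(seed) % (2**31),
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        S = ica.fit_transform(X.T)  # (L, M): sources over edges
    converged = not any(
        issubclass(w.category, ConvergenceWarning) for w in caught
    )
    A = ica.mixing_  # (P, M)
    norms = np.linalg.norm(S, axis=0)
    norms[norms == 0] = 1.0
    components = (S / norms).T  # (M, L) unit rows
    weights = A * norms  # scale moved onto weights
    if profile_indices is None:
        profile_indices = np.arange(P)
    return RunResult(
        run_id=run_id,
        profile_indices=np.asarray(profile_indices, dtype=int),
        components=components,
        weights=weights,
        converged=bool(converged),
        seed=int(seed),
    )


def cluster_robust_traits(
    runs: Sequence[RunResult],
    r_thresh: float = 0.5,
    freq_thresh: float = 0.50,
    n_profiles: int | None = None,
    include_nonconverged: bool = True,
) -> list[RobustTrait]:
    """Greedy cross-run clustering of ICA components into robust traits.

    Components from all runs are pooled (with ``include_nonconverged=False``
    only runs whose fixed-point iteration converged; by default
    non-converged runs are kept, since cross-run replication — not the
    run-level fixed-point flag — is the stability criterion, and with more
    components than non-Gaussian sources the surplus components prevent the
    run-level flag from ever being set).  Repeatedly, the
    yet-unclustered component with matches (|Pearson r| >= ``r_thresh``) in
    the largest number of other runs seeds a cluster; each run contributes at
    most its best-matching component.  Members are sign-flipped to correlate
    positively with the seed, the trait is their exact mean, and weights are
    averaged per profile over the member runs that sampled it.  Clusters
    appearing in fewer than ``freq_thresh`` of the converged runs are
    discarded.  Output is sorted by frequency, descending.
    """
    converged = [r for r in runs
                 if include_nonconverged or r.converged]
    if len(converged) < 2:
        warnings.warn(
            "cluster_robust_traits: fewer than 2 usable runs; no robust "
            "trait can be identified"
        )
        return []
    if n_profiles is None:
        n_profiles = int(max(r.profile_indices.max() for r in converged)) + 1

    comp_run: list[int] = []       # pool position -> run index (into converged)
    comp_id: list[int] = []        # pool position -> component row in its run
    stack = []
    for ri, r in enumerate(converged):
        for ci in range(r.components.shape[0]):
            comp_run.append(ri)
            comp_id.append(ci)
            stack.append(r.components[ci])
    C = np.vstack(stack)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(C)
    corr = np.nan_to_num(corr)
    abs_corr = np.abs(corr)
    n_pool = len(comp_run)
    comp_run_arr = np.array(comp_run)
    unclustered = np.ones(n_pool, dtype=bool)
    n_runs = len(converged)

    clusters: list[RobustTrait] = []
    while unclustered.any():
        avail = np.flatnonzero(unclustered)
        # matches: number of distinct OTHER runs holding an unclustered
        # component correlated at |r| >= r_thresh
        best_seed, best_matches = avail[0], -1
        for c in avail:
            hit = avail[(abs_corr[c, avail] >= r_thresh) & (comp_run_arr[avail] != comp_run_arr[c])]
            n_match = len(set(comp_run_arr[hit].tolist()))
            if n_match > best_matches:
                best_seed, best_matches = c, n_match
        seed = best_seed
        members: list[int] = []
        for ri in range(n_runs):
            cand = avail[comp_run_arr[avail] == ri]
            if cand.size == 0:
                continue
            if ri == comp_run_arr[seed]:
                members.append(int(seed))
                continue
            ok = cand[abs_corr[seed, cand] >= r_thresh]
            if ok.size:
                members.append(int(ok[np.argmax(abs_corr[seed, ok])]))
        signs = {m: (1 if corr[seed, m] >= 0 else -1) for m in members}
        vec = np.mean([signs[m] * C[m] for m in members], axis=0)
        w_sum = np.zeros(n_profiles)
        w_count = np.zeros(n_profiles, dtype=int)
        member_info = []
        for m in members:
            r = converged[comp_run_arr[m]]
            w = signs[m] * r.weights[:, comp_id[m]]
            w_sum[r.profile_indices] += w
            w_count[r.profile_indices] += 1
            member_info.append(
                (r.run_id, comp_id[m], float(corr[seed, m]), signs[m])
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            w_mean = np.where(w_count > 0, w_sum / np.maximum(w_count, 1), np.nan)
        clusters.append(
            RobustTrait(
                vector=vec,
                weights=w_mean,
                counts=w_count,
                frequency=len(members) / n_runs,
                members=member_info,
            )
        )
        unclustered[members] = False

    robust = [c for c in clusters if c.frequency >= freq_thresh]
    robust.sort(key=lambda t: -t.frequency)
    return robust


def decompose(
    hybrid: HybridDataset, config: DecompositionConfig
) -> tuple[list[RobustTrait], dict]:
    """Full decomposition: PCA denoise, bootstrap ICA runs, clustering.

    The master seed deterministically spawns one (cohort, ICA) seed pair per
    run; the seed chain is reported in the diagnostics.
    """
    denoised, k, cum = pca_denoise(hybrid.data, config.variance_fraction)
    if config.n_components > k:
        raise DecompositionError(
            f"decompose: M = {config.n_components} exceeds post-PCA rank {k}"
        )
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(config.n_runs)
    runs: list[RunResult] = []
    run_seeds: list[dict] = []
    for i, child in enumerate(children):
        cohort_ss, ica_ss = child.spawn(2)
        rng = np.random.default_rng(cohort_ss)
        rows = sample_run_cohort(
            hybrid.subjects, hybrid.conditions, config.n_per_condition, rng
        )
        ica_seed = int(ica_ss.generate_state(1)[0] % (2**31))
        run = run_ica(
            denoised[rows],
            config.n_components,
            seed=ica_seed,
            fun=config.fun,
            max_iter=config.max_iter,
            tol=config.tol,
            profile_indices=rows,
            run_id=i,
        )
        runs.append(run)
        run_seeds.append({"run": i, "ica_seed": ica_seed})
    traits = cluster_robust_traits(
        runs,
        r_thresh=config.r_thresh,
        freq_thresh=config.freq_thresh,
        n_profiles=hybrid.n_profiles,
        include_nonconverged=not config.discard_nonconverged,
    )
    diagnostics = {
        "k_retained": k,
        "explained_curve": cum,
        "n_runs": config.n_runs,
        "n_converged": sum(r.converged for r in runs),
        "run_seeds": run_seeds,
        "runs": runs,
        "n_robust": len(traits),
        "frequencies": [t.frequency for t in traits],
    }
    return traits, diagnostics


def select_model_order(
    hybrid: HybridDataset,
    M_range: Sequence[int],
    config: DecompositionConfig,
    icc_threshold: float = 0.5,
) -> tuple[int, pd.DataFrame]:
    """Scan model orders; keep the M maximizing robust task-sensitive traits.

    Score per M = number of robust traits with weight ICC >= the threshold;
    ties broken by higher mean ICC of robust traits, then by smaller M.
    """
    from .task_sensitivity import classify_task_sensitive

    M_range = sorted(set(int(m) for m in M_range))
    if not M_range:
        raise DecompositionError("select_model_order: empty M range")
    _, k, _ = pca_denoise(hybrid.data, config.variance_fraction)
    rows = []
    best = None
    for M in M_range:
        if M < 2 or M > k:
            raise DecompositionError(
                f"select_model_order: M = {M} outside [2, post-PCA rank {k}]"
            )
        traits, diag = decompose(hybrid, replace(config, n_components=M))
        if traits:
            reports = classify_task_sensitive(
                traits, hybrid.conditions, icc_threshold=icc_threshold
            )
            iccs = [r.icc for r in reports]
            score = sum(r.sensitive for r in reports)
            mean_icc = float(np.mean(iccs))
        else:
            score, mean_icc = 0, np.nan
        rows.append(
            {
                "M": M,
                "n_robust": len(traits),
                "n_task_sensitive": score,
                "mean_icc": mean_icc,
                "n_converged": diag["n_converged"],
            }
        )
        key = (score, -1e9 if np.isnan(mean_icc) else mean_icc, -M)
        if best is None or key > best[0]:
            best = (key, M)
    table = pd.DataFrame(rows)
    if table["n_task_sensitive"].max() == 0:
        warnings.warn(
            "select_model_order: no task-sensitive robust trait at any M; "
            "returning the smallest candidate order"
        )
        return M_range[0], table
    return best[1], table
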