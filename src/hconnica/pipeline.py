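"""One-call orchestration of the full hybrid decomposition workflow.

normalize SC -> common-edge mask -> structural correlation -> hybrid
assembly -> PCA + bootstrap FastICA + robustness clustering -> ICC task
scoring -> joint FC-SC masks and nodal strengths, with a machine-readable
run report.  Every stage is also available on its own (this module is a thin
composition of the stage functions), and a rerun with the same seed
reproduces the same report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .connectome import (
    Connectome,
    ConnectomeError,
    Modality,
    read_cohort_manifest,
    read_connectome,
    read_node_partition,
)
from .decomposition import DecompositionConfig, RobustTrait, decompose
from .hybrid import EdgeIndex, HybridDataset, assemble_hybrid, devectorize_trait
from .sc_transform import EdgeMask, common_edge_mask, log_transform, structural_correlation
from .task_sensitivity import SensitivityReport, classify_task_sensitive
from .trait_mapping import JointMask, joint_fc_sc_mask, nodal_strength

log = logging.getLogger("hconnica")


@dataclass
class PipelineConfig:
    """Resolved parameters of a pipeline run (embedded in every report)."""

    variance_fraction: float = 0.90
    n_components: int = 10
    n_runs: int = 100
    r_thresh: float = 0.5
    freq_thresh: float = 0.50
    n_per_condition: int = 10
    fun: str = "logcosh"
    max_iter: int = 500
    tol: float = 1e-6
    icc_threshold: float = 0.5
    percentile_lo: float = 5.0
    percentile_hi: float = 95.0
    n_swaps: int = 50_000
    exclude_pair_entries: bool = False
    log_transform_sc: bool = True
    seed: int = 0

    def decomposition_config(self) -> DecompositionConfig:
        return DecompositionConfig(
            n_components=self.n_components,
            variance_fraction=self.variance_fraction,
            n_runs=self.n_runs,
            r_thresh=self.r_thresh,
            freq_thresh=self.freq_thresh,
            n_per_condition=self.n_per_condition,
            fun=self.fun,
            max_iter=self.max_iter,
            tol=self.tol,
            seed=self.seed,
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    hybrid: HybridDataset
    mask: EdgeMask
    traits: list[RobustTrait]
    reports: list[SensitivityReport]
    joint_masks: list[JointMask]
    diagnostics: dict
    config: PipelineConfig

    def report_dict(self) -> dict:
        """JSON-serializable run report."""
        return {
            "config": json.loads(self.config.to_json()),
            "config_hash": self.config.config_hash,
            "n_profiles": self.hybrid.n_profiles,
            "n_nodes": self.hybrid.edge_index.n_nodes,
            "l_fc": self.hybrid.edge_index.l_fc,
            "l_sc": self.hybrid.edge_index.l_sc,
            "edge_mask_density": self.mask.density,
            "k_retained": self.diagnostics["k_retained"],
            "n_runs": self.diagnostics["n_runs"],
            "n_converged": self.diagnostics["n_converged"],
            "n_robust_traits": len(self.traits),
            "traits": [
                {
                    "trait_id": r.trait_id,
                    "frequency": self.traits[r.trait_id].frequency,
                    "icc": r.icc,
                    "task_sensitive": r.sensitive,
                    "joint_mask_edges": self.joint_masks[r.trait_id].joint_count,
                }
                for r in self.reports
            ],
            "run_seeds": self.diagnostics["run_seeds"],
        }


def run_hybrid_pipeline(
    fcs: Sequence[Connectome],
    scs: Sequence[Connectome],
    subjects: Sequence[str],
    conditions: Sequence[str],
    config: PipelineConfig,
) -> PipelineResult:
    """Run the full method on in-memory cohort connectomes.

    ``fcs``/``scs`` are aligned per profile (the SC of profile p is the
    structural connectome of that subject; repeats across conditions are
    fine and are normalized once per distinct subject).
    """
    if len(set(conditions)) < 2:
        raise ConnectomeError(
            "task sensitivity requires >= 2 conditions (groups) in the cohort"
        )
    log.info("stage 1/5: SC normalization (%d profiles)", len(fcs))
    logged: dict[str, Connectome] = {}
    for sc in scs:
        if sc.subject_id not in logged:
            logged[sc.subject_id] = (
                log_transform(sc) if config.log_transform_sc else sc
            )
    mask = common_edge_mask(list(logged.values()))
    log.info("common-edge mask: %d pairs (density %.1f%%)",
             mask.count, 100 * mask.density)
    sc_corrs = {
        sid: structural_correlation(
            sc, mask, exclude_pair_entries=config.exclude_pair_entries
        )
        for sid, sc in logged.items()
    }
    log.info("stage 2/5: hybrid assembly")
    idx = EdgeIndex.from_mask(mask)
    profiles = [
        (str(subjects[p]), str(conditions[p]), fcs[p],
         sc_corrs[scs[p].subject_id])
        for p in range(len(fcs))
    ]
    hybrid = assemble_hybrid(profiles, idx)
    log.info("stage 3/5: decomposition (M=%d, %d runs)",
             config.n_components, config.n_runs)
    traits, diagnostics = decompose(hybrid, config.decomposition_config())
    log.info("found %d robust traits (of %d converged runs)",
             len(traits), diagnostics["n_converged"])
    log.info("stage 4/5: task sensitivity (ICC)")
    reports = classify_task_sensitive(
        traits, hybrid.conditions, icc_threshold=config.icc_threshold
    )
    log.info("stage 5/5: joint FC-SC masks")
    joint_masks = [
        joint_fc_sc_mask(t.vector, idx, config.percentile_lo,
                         config.percentile_hi)
        for t in traits
    ]
    return PipelineResult(
        hybrid=hybrid, mask=mask, traits=traits, reports=reports,
        joint_masks=joint_masks, diagnostics=diagnostics, config=config,
    )


def run_pipeline(
    manifest_path: str | Path,
    partition_path: str | Path | None,
    config: PipelineConfig,
    out_dir: str | Path,
) -> dict:
    """File-level pipeline: read a cohort manifest, write all artifacts.

    Artifacts: ``traits.tsv`` (edges x traits), ``weights.tsv`` (profiles x
    traits), ``edge_mask.csv``, per-trait joint-mask TSVs and nodal-strength
    CSVs, and ``report.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = read_cohort_manifest(manifest_path)
    fcs, scs = [], []
    sc_cache: dict[str, Connectome] = {}
    for _, row in manifest.frame.iterrows():
        fcs.append(read_connectome(
            manifest.resolve(row["fc_path"]), Modality.FC,
            subject_id=row["subject_id"], condition=row["condition"],
        ))
        sc_path = str(manifest.resolve(row["sc_path"]))
        if sc_path not in sc_cache:
            sc_cache[sc_path] = read_connectome(
                sc_path, Modality.SC_RAW, subject_id=row["subject_id"],
            )
        scs.append(sc_cache[sc_path])
    if partition_path is not None:
        partition = read_node_partition(partition_path)
        partition.validate_against(fcs[0].node_labels)
    result = run_hybrid_pipeline(
        fcs, scs, manifest.subjects, manifest.conditions, config
    )
    _write_artifacts(result, out_dir)
    report = result.report_dict()
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report


def _write_artifacts(result: PipelineResult, out_dir: Path) -> None:
    idx = result.hybrid.edge_index
    labels = result.hybrid.node_labels
    if result.traits:
        T = np.column_stack([t.vector for t in result.traits])
        cols = [f"trait{j}" for j in range(len(result.traits))]
        pd.DataFrame(T, columns=cols).to_csv(
            out_dir / "traits.tsv", sep="\t", index=False
        )
        W = np.column_stack([t.weights for t in result.traits])
        wdf = pd.DataFrame(W, columns=cols)
        wdf.insert(0, "subject_id", result.hybrid.subjects)
        wdf.insert(1, "condition", result.hybrid.conditions)
        wdf.to_csv(out_dir / "weights.tsv", sep="\t", index=False)
    pairs = result.mask.pairs()
    pd.DataFrame({
        "i_label": [labels[i] for i in pairs[:, 0]],
        "j_label": [labels[j] for j in pairs[:, 1]],
    }).to_csv(out_dir / "edge_mask.csv", index=False)
    for j, jm in enumerate(result.joint_masks):
        np.savetxt(out_dir / f"joint_mask_trait{j}.tsv",
                   jm.matrix.astype(int), fmt="%d", delimiter="\t")
        strength = nodal_strength(jm)
        pd.DataFrame({"node_label": labels, "strength": strength}).to_csv(
            out_dir / f"strength_trait{j}.csv", index=False
        )
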