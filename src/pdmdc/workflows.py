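"""End-to-end pipelines: preprocessing → fitting → reports.

Two workflows mirror the two uses of the model:

* :func:`run_prediction_workflow` — preprocess, resample observation
  splits, select the truncation rank, fit the pooled full-state model
  and report test R² per iteration;
* :func:`run_metabotyping_workflow` — preprocess, compute the shared
  basis (scree-suggested or configured latent dimension), fit
  per-individual latent models, cluster per-(state, diet) cosine
  similarities, run the CP comparator, and report cluster overlap and
  clinical ANOVA.

Each run writes a manifest (config, seeds, package version) so outputs
are reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .data_model import (
    ClinicalTable,
    DietInputMatrix,
    ResponseTensor,
    filter_low_variance,
    standardize_per_diet,
    subtract_baseline,
)
from .evaluation import ExperimentReport, resampling_experiment
from .metabotyping import (
    anova_association,
    cluster_cp_scores,
    cluster_overlap,
    cluster_similarity,
    cosine_similarity_matrix,
    cp_als,
    extract_state_trajectories,
    scree_inflection,
)
from .parametric import compute_shared_basis, fit_shared_latent

__all__ = ["WorkflowConfig", "preprocess", "run_prediction_workflow",
           "run_metabotyping_workflow"]

_KNOWN_KEYS = {
    "variance_threshold", "downsample_to", "standardize_mode",
    "fractions", "n_iter", "seed", "tol",
    "n_states", "n_clusters", "cp_components", "cp_starts",
    "degeneracy_threshold",
}


@dataclass(frozen=True)
class WorkflowConfig:
    """Validated parameters for both pipelines; unknown keys rejected."""

    variance_threshold: float | None = None
    downsample_to: int | None = None
    standardize_mode: str = "per_metabolite"
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    n_iter: int = 100
    seed: int = 0
    tol: float = 0.30
    n_states: int | None = None   # None → scree-suggested
    n_clusters: int = 2
    cp_components: int = 5
    cp_starts: int = 3
    degeneracy_threshold: float = 0.85

    def __post_init__(self) -> None:
        if min(self.fractions) < 0 or abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must be nonnegative and sum to 1")
        if self.fractions[2] == 0:
            raise ValueError("test fraction must be positive for evaluation")
        object.__setattr__(self, "fractions", tuple(self.fractions))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorkflowConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def preprocess(tensor: ResponseTensor, cfg: WorkflowConfig) -> ResponseTensor:
    """Apply the standard chain: variance filter → baseline subtraction
    → log down-sampling → per-diet standardization (in that order;
    filtering and down-sampling run on raw concentrations)."""
    out = tensor
    if cfg.variance_threshold is not None:
        out = filter_low_variance(out, cfg.variance_threshold)
    out = subtract_baseline(out)
    if cfg.downsample_to is not None and cfg.downsample_to < out.n_times:
        from .data_model import downsample_logarithmic
        out = downsample_logarithmic(out, cfg.downsample_to)
    out, _ = standardize_per_diet(out, mode=cfg.standardize_mode)
    return out


def _write_manifest(out_dir: Path, cfg: WorkflowConfig, extra: dict) -> None:
    manifest = {"config": cfg.to_dict(), "package_version": __version__, **extra}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_prediction_workflow(
    tensor: ResponseTensor,
    diets: DietInputMatrix,
    cfg: WorkflowConfig,
    out_dir: str | Path | None = None,
) -> ExperimentReport:
    """Preprocess, then run the resampling prediction protocol."""
    processed = preprocess(tensor, cfg)
    report = resampling_experiment(processed, diets, n_iter=cfg.n_iter,
                                   seed=cfg.seed, fractions=cfg.fractions,
                                   tol=cfg.tol)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_manifest(out_dir, cfg, {"selected_ranks": report.selected_ranks,
                                       "iteration_seeds": report.seeds})
        (out_dir / "prediction_report.json").write_text(json.dumps({
            "mean_r2": report.mean_r2,
            "r2_per_iteration": report.r2_per_iteration,
            "selected_ranks": report.selected_ranks,
        }, indent=2))
        import pandas as pd
        pd.DataFrame({"iteration": range(len(report.r2_per_iteration)),
                      "r2": report.r2_per_iteration,
                      "selected_rank": report.selected_ranks}
                     ).to_csv(out_dir / "prediction_report.csv", index=False)
    return report


@dataclass
class MetabotypingResult:
    """Labels and diagnostics from the metabotyping pipeline."""

    n_states: int
    scree: dict
    pdmdc_labels: dict              # (state, diet_id) → label array
    cp_labels: np.ndarray
    cp_explained_variance: float
    cp_degenerate: bool
    overlap: dict                   # (state, diet_id) → overlap dict vs CP
    anova: list[dict] = field(default_factory=list)


def run_metabotyping_workflow(
    tensor: ResponseTensor,
    diets: DietInputMatrix,
    cfg: WorkflowConfig,
    clinical: ClinicalTable | None = None,
    out_dir: str | Path | None = None,
) -> MetabotypingResult:
    """Preprocess, fit the shared-basis latent models, cluster latent
    trajectories per (state, diet), run the CP comparator and compare."""
    processed = preprocess(tensor, cfg)
    M = processed.n_metabolites
    X_tot = processed.values.reshape(M, -1)
    spectrum = np.linalg.svd(X_tot, compute_uv=False)
    if cfg.n_states is not None:
        S = cfg.n_states
        scree_info = {"spectrum": spectrum, "configured": True}
    else:
        S, scree_info = scree_inflection(spectrum)

    basis = compute_shared_basis(processed, S)
    models = fit_shared_latent(processed, diets, basis)
    trajset = extract_state_trajectories(models, diets, processed.n_times)

    k = cfg.n_clusters
    if k >= processed.n_individuals:
        warnings.warn("n_clusters equals the number of individuals: singleton clusters",
                      stacklevel=2)
        k = processed.n_individuals

    pdmdc_labels = {}
    for s in range(S):
        for d, diet_id in enumerate(processed.diet_ids):
            sim = cosine_similarity_matrix(trajset, s, d)
            pdmdc_labels[(s, diet_id)] = cluster_similarity(sim, k)

    # CP comparator runs on the per-metabolite unit-variance tensor
    scaled = processed.values / processed.values.reshape(M, -1).std(axis=1, ddof=1)[
        :, None, None, None]
    cp = cp_als(scaled, cfg.cp_components, n_starts=cfg.cp_starts, seed=cfg.seed)
    cp_labels = cluster_cp_scores(cp, k, seed=cfg.seed, normalize=True)

    overlap = {key: cluster_overlap(lab, cp_labels)
               for key, lab in pdmdc_labels.items()}

    anova = []
    if clinical is not None:
        best_key = max(overlap, key=lambda kk: overlap[kk]["percent"])
        anova = anova_association(pdmdc_labels[best_key], clinical)
    result = MetabotypingResult(S, scree_info, pdmdc_labels, cp_labels,
                                cp.explained_variance, cp.degenerate, overlap, anova)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_manifest(out_dir, cfg, {"n_states": S})
        import pandas as pd
        rows = [{"state": s, "diet": d_id,
                 "labels": list(map(int, lab)),
                 "overlap_vs_cp_percent": overlap[(s, d_id)]["percent"]}
                for (s, d_id), lab in pdmdc_labels.items()]
        (out_dir / "metabotyping_report.json").write_text(json.dumps({
            "n_states": S,
            "cp_explained_variance": cp.explained_variance,
            "cp_degenerate": cp.degenerate,
            "cp_labels": list(map(int, cp_labels)),
            "clusters": rows,
            "anova": anova,
        }, indent=2))
        pd.DataFrame({"singular_value": spectrum}).to_csv(
            out_dir / "scree_spectrum.csv", index_label="component")
    return result
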