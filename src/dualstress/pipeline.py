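"""End-to-end pipeline runs driven by a flat config, with a manifest.

The microarray pipeline chains filter -> normalize -> collapse -> stage1 ->
stage2 -> adjust -> fdr -> counts -> cluster; the metabolite pipeline
chains normalize -> partition -> fit -> adjust.  Every stage's row
accounting lands in the manifest, any stage failure aborts with the stage
name, and a run is fully reproducible from config + seed (no timestamps in
any output).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as _cluster
from . import diffexpr, io, metabolomics, preprocess, simulate
from .errors import DualstressError, ValidationError

__all__ = [
    "RunConfig",
    "StageError",
    "MicroarrayResult",
    "MetaboliteResult",
    "run_microarray_pipeline",
    "run_metabolite_pipeline",
    "MICROARRAY_STAGES",
    "METABOLITE_STAGES",
]

log = logging.getLogger("dualstress")

MICROARRAY_STAGES = ("filter", "normalize", "collapse", "stage1", "stage2",
                     "adjust", "fdr", "counts", "cluster")
METABOLITE_STAGES = ("normalize", "partition", "fit", "adjust")

_CHOICES = {
    "threshold_rule": {"scaled", "plain"},
    "grouping": {"run_rep", "run"},
    "cluster_standardize": {"zscore", "pca", "none"},
    "treatment_distance": {"pearson", "covariance"},
    "treatment_linkage": {"single", "complete", "average", "ward"},
    "scaling": {"fraction_max", "sample_total"},
}


class StageError(DualstressError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Flat, human-readable run configuration (YAML-compatible)."""

    seed: int = simulate.DEFAULT_SEED
    out_dir: str | None = None
    # inputs: either synthetic specs or file paths (never neither)
    synthetic: bool = True
    spot_dir: str | None = None
    sample_sheet: str | None = None
    array_design: dict = field(default_factory=dict)
    effects: dict = field(default_factory=dict)
    metab_design: dict = field(default_factory=dict)
    # metabolite file inputs (CSV; used when synthetic=false)
    metab_areas: str | None = None
    metab_samples: str | None = None
    metab_standards: str | None = None
    metab_rt: str | None = None
    # preprocessing
    threshold_rule: str = "scaled"
    min_spots: int = 10
    # modelling
    grouping: str = "run_rep"
    alpha: float = 0.05
    count_threshold: float = 0.001
    adjust: bool = True
    pairwise: bool = False
    # clustering
    cluster_k: int = 6
    cluster_standardize: str = "zscore"
    treatment_distance: str = "pearson"
    treatment_linkage: str = "average"
    # metabolomics
    presence_threshold: float = 0.90
    detection_floor: float = 0.0
    scaling: str = "fraction_max"

    def __post_init__(self):
        if not self.synthetic and not (self.spot_dir and self.sample_sheet):
            raise ValidationError(
                "config needs either synthetic=true or spot_dir + sample_sheet"
            )
        for name, allowed in _CHOICES.items():
            if getattr(self, name) not in allowed:
                raise ValidationError(
                    f"{name} must be one of {sorted(allowed)}, "
                    f"got {getattr(self, name)!r}"
                )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class MicroarrayResult:
    log_ratios: pd.DataFrame
    rejections: pd.DataFrame
    stage1: diffexpr.Stage1Fit
    fits: list
    probe_table: pd.DataFrame
    fdr_selected: list
    fdr_threshold: float
    de_summary: diffexpr.DESummary
    tree: object
    assignment: object
    manifest: dict
    recovery: dict | None = None
    experiment: simulate.ArrayExperiment | None = None


@dataclass
class MetaboliteResult:
    normalized: pd.DataFrame
    classes: pd.Series
    fits: list
    table: pd.DataFrame
    presence: pd.DataFrame
    manifest: dict
    recovery: dict | None = None
    experiment: simulate.MetaboliteExperiment | None = None


def _stage(manifest: dict, name: str, **info):
    manifest["stages"].append({"stage": name, **info})
    log.info("stage %-9s %s", name, info)


def _load_array_inputs(cfg: RunConfig):
    if cfg.synthetic:
        design = simulate.ArrayDesignSpec(**{**cfg.array_design, "seed": cfg.seed})
        effects = simulate.EffectSpec(**cfg.effects)
        exp = simulate.generate_array_experiment(design, effects, seed=cfg.seed)
        return exp.spots, exp.sample_sheet, exp
    sheet = io.read_sample_sheet(cfg.sample_sheet)
    frames = [io.read_spot_table(p) for p in sorted(Path(cfg.spot_dir).glob("*.gpr.txt"))]
    if not frames:
        raise ValidationError(f"no .gpr.txt files under {cfg.spot_dir}")
    return pd.concat(frames, ignore_index=True), sheet, None


def run_microarray_pipeline(cfg: RunConfig) -> MicroarrayResult:
    """Execute the nine-stage microarray analysis described in the module doc."""
    manifest: dict = {"pipeline": "microarray", "seed": cfg.seed,
                      "config": cfg.to_dict(), "stages": []}
    spots, sheet, exp = _load_array_inputs(cfg)

    stage = "filter"
    try:
        kept, rejections = preprocess.filter_spots(spots, cfg.threshold_rule)
        _stage(manifest, stage, rows_in=len(spots), rows_kept=len(kept),
               rows_rejected=len(rejections))

        stage = "normalize"
        lr, dropped = preprocess.compute_log_ratios(kept, cfg.min_spots)
        rejections = pd.concat([rejections, dropped], ignore_index=True)
        _stage(manifest, stage, rows_in=len(kept), rows_kept=len(lr),
               rows_rejected=len(dropped))

        stage = "collapse"
        lr = preprocess.collapse_duplicates(lr)
        _stage(manifest, stage, rows_out=len(lr),
               unique_probes=int(lr["probe_id"].nunique()))

        stage = "stage1"
        s1 = diffexpr.fit_stage1(lr, sheet)
        _stage(manifest, stage, arrays=len(s1.array_effects),
               var_array=s1.var_array, var_resid=s1.var_resid)

        stage = "stage2"
        fits = diffexpr.fit_stage2(s1.residuals, sheet, cfg.grouping)
        _stage(manifest, stage, probes=len(fits),
               ols_fallbacks=int(sum(f.used_ols for f in fits)),
               incomplete=int(sum(f.incomplete for f in fits)))

        stage = "adjust"
        if cfg.adjust:
            diffexpr.adjust_pvalues(fits, pairwise=cfg.pairwise)
        _stage(manifest, stage, applied=cfg.adjust, pairwise=cfg.pairwise)

        stage = "fdr"
        p_int = pd.Series({f.probe_id: f.f_tests["trt_time"][3] for f in fits})
        selected, thr = diffexpr.fdr_select(p_int, cfg.alpha)
        _stage(manifest, stage, alpha=cfg.alpha, selected=len(selected),
               bh_threshold=thr)

        stage = "counts"
        de = diffexpr.count_de(fits, cfg.count_threshold)
        _stage(manifest, stage, threshold=cfg.count_threshold,
               overlaps=de.overlaps["n_overlap"].tolist())

        stage = "cluster"
        sel = set(selected)
        vec_rows = {
            f.probe_id: f.cell_means for f in fits
            if f.probe_id in sel and np.all(np.isfinite(f.cell_means))
        }
        tree = assign = None
        if len(vec_rows) >= 2:
            cols = [f"{t}_{h:g}h" for (t, h) in fits[0].cells]
            vectors = pd.DataFrame.from_dict(vec_rows, orient="index", columns=cols)
            tree, assign = _cluster.cluster_probes(
                vectors, cfg.cluster_standardize, cfg.cluster_k
            )
            _stage(manifest, stage, clustered=len(vectors),
                   excluded=len(selected) - len(vectors), k=assign.k)
        else:
            _stage(manifest, stage, clustered=0, excluded=len(selected),
                   skipped="fewer than 2 complete selected vectors")
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError(stage, exc) from exc

    recovery = None
    if exp is not None:
        truth = exp.truth.set_index("probe_id")
        true_pos = set(truth.index[truth["is_differential"]])
        sel = set(selected)
        tp = len(sel & true_pos)
        recovery = {
            "n_true_differential": len(true_pos),
            "n_selected": len(sel),
            "sensitivity": tp / len(true_pos) if true_pos else np.nan,
            "fdp": (len(sel) - tp) / len(sel) if sel else 0.0,
        }
        manifest["recovery"] = recovery

    probe_table = diffexpr.stage2_table(fits)
    result = MicroarrayResult(lr, rejections, s1, fits, probe_table,
                              selected, thr, de, tree, assign, manifest,
                              recovery, exp)
    if cfg.out_dir:
        tables = {
            "log_ratios": lr,
            "rejections": rejections,
            "probe_fits": probe_table,
            "fdr_selected": pd.DataFrame({"probe_id": selected}),
            "de_counts": de.counts,
            "de_overlaps": de.overlaps,
        }
        if assign is not None:
            tables["cluster_assignments"] = (
                assign.labels.rename_axis("probe_id").reset_index()
            )
            Path(cfg.out_dir).mkdir(parents=True, exist_ok=True)
            (Path(cfg.out_dir) / "probe_tree.nwk").write_text(tree.newick() + "\n")
        written = io.write_results(tables, cfg.out_dir, params=manifest, seed=cfg.seed)
        manifest["files"] = written["files"]
    return result


def run_metabolite_pipeline(cfg: RunConfig) -> MetaboliteResult:
    """Execute normalize -> partition -> fit -> adjust on the peak table."""
    manifest: dict = {"pipeline": "metabolite", "seed": cfg.seed,
                      "config": cfg.to_dict(), "stages": []}
    if cfg.synthetic or not cfg.metab_areas:
        spec = simulate.MetabDesignSpec(**{**cfg.metab_design, "seed": cfg.seed})
        exp = simulate.generate_metabolite_experiment(spec, seed=cfg.seed)
    else:
        areas = pd.read_csv(cfg.metab_areas).set_index("sample_id")
        samples = pd.read_csv(cfg.metab_samples)
        standards = pd.read_csv(cfg.metab_standards)
        rt = pd.read_csv(cfg.metab_rt).set_index("fraction")["rt"]
        exp = simulate.MetaboliteExperiment(
            samples, areas, rt, standards,
            truth=pd.DataFrame(columns=["fraction"]), spec=None, seed=cfg.seed,
        )

    stage = "normalize"
    try:
        norm = metabolomics.normalize_peak_areas(
            exp.areas, exp.samples, exp.fraction_rt, exp.standards, cfg.scaling
        )
        _stage(manifest, stage, samples=len(norm), fractions=norm.shape[1])

        stage = "partition"
        classes = metabolomics.partition_metabolites(
            norm, cfg.presence_threshold, cfg.detection_floor
        )
        n_cont = int((classes == "continuous").sum())
        _stage(manifest, stage, continuous=n_cont,
               dichotomous=int(len(classes) - n_cont))

        stage = "fit"
        fits = metabolomics.fit_metabolite_model(
            norm, exp.samples, classes, cfg.detection_floor, pairwise=cfg.pairwise
        )
        _stage(manifest, stage, fitted=int(sum(
            f.metab_class == "continuous" and f.testable for f in fits)))

        stage = "adjust"
        # Tukey adjustment happens inside the per-fraction fit; record it
        _stage(manifest, stage, applied=True)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    table = metabolomics.metabolite_table(fits)
    dich = [f.fraction for f in fits if f.metab_class == "dichotomous"]
    presence = metabolomics.presence_table(norm, exp.samples, dich,
                                           cfg.detection_floor)
    recovery = None
    if exp.truth is not None and "is_dichotomous" in exp.truth.columns:
        truth = exp.truth.set_index("fraction")
        est = table.set_index("fraction")
        cont = [f.fraction for f in fits
                if f.metab_class == "continuous" and f.testable]
        err = (est.loc[cont, "beta_tc"] - truth.loc[cont, "beta_tc"]).abs()
        recovery = {
            "n_continuous_fitted": len(cont),
            "max_abs_beta_tc_error": float(err.max()) if len(err) else np.nan,
            "dichotomous_truth_agreement": float(
                (est["class"].eq("dichotomous") == truth["is_dichotomous"]).mean()
            ),
        }
        manifest["recovery"] = recovery

    result = MetaboliteResult(norm, classes, fits, table, presence, manifest,
                              recovery, exp)
    if cfg.out_dir:
        tables = {
            "normalized_areas": norm.reset_index(),
            "metabolite_classes": classes.rename_axis("fraction").reset_index(),
            "metabolite_fits": table,
            "presence_counts": presence,
        }
        written = io.write_results(tables, cfg.out_dir, params=manifest, seed=cfg.seed)
        manifest["files"] = written["files"]
    return result
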