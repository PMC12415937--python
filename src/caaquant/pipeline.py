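"""Configuration-driven pipeline: simulate -> segment -> quantify -> fit -> report.

Each stage consumes and produces only declared files under the output
directory, so a downstream stage rerun on cached upstream output is
bit-identical to the full run.  All randomness flows from a single seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import imaging, quantify, segmentation
from .detection import DetectionParams, detect_amyloid
from .glmm import (GLMMOptions, ModelData, estimated_marginal_means,
                   fit_tweedie_glmm, fit_zib_glmm)
from .quantify import StudyTable, measure_image, preprocess_study_table
from .segmentation import SegmentationParams, segment_vessels
from .simulate import SceneConfig, StudyConfig, render_synthetic_image

log = logging.getLogger("caaquant")

STAGES = ("simulate", "segment", "quantify", "fit", "report")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Exactly one of ``input_images`` (paths to acquired TIFFs, with group and
    mouse identifiers) or ``simulation`` (a synthetic-study block) must be
    given.
    """

    outdir: str = "results/pipeline"
    seed: int = 0
    input_images: list | None = None          # [{path, group, mouse_id, image_id}]
    simulation: dict | None = None            # StudyConfig / SceneConfig overrides
    segmentation: dict = field(default_factory=dict)
    detection: dict = field(default_factory=dict)
    statistics: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_images is None) == (self.simulation is None):
            raise ValueError(
                "exactly one of input_images or simulation must be configured"
            )
        if self.input_images:
            for entry in self.input_images:
                missing = {"path", "group", "mouse_id", "image_id"} - set(entry)
                if missing:
                    raise ValueError(f"input image entry missing {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def segmentation_params(self) -> SegmentationParams:
        return SegmentationParams(**self.segmentation)

    def detection_params(self) -> DetectionParams:
        return DetectionParams(**self.detection)

    def study_config(self) -> StudyConfig:
        sim = dict(self.simulation or {})
        scene = SceneConfig(**sim.pop("scene", {}))
        return StudyConfig(scene=scene, **{
            k: v for k, v in sim.items()
            if k in ("mice_per_group", "images_per_mouse")
        })


def _image_manifest(config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    return pd.read_csv(outdir / "images.csv")


def run_simulate(config: PipelineConfig) -> pd.DataFrame:
    """Render the synthetic scenes and write them plus a manifest."""
    outdir = Path(config.outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    study = config.study_config()
    rng = np.random.default_rng(config.seed)
    rows = []
    truth_v, truth_a = [], []
    for g, gname in enumerate(study.groups):
        scene = study.scene
        if g == 1:
            # treatment scenes carry the generative group effect on
            # aggregate size (multiplicative, log-link scale)
            ratio = float(np.exp(study.intramural.beta1))
            lo, hi = scene.aggregate_size_px
            scene = replace(scene, aggregate_size_px=(max(lo * ratio, 2.0),
                                                      max(hi * ratio, 4.0)))
        for m in range(study.mice_per_group):
            mouse_id = f"{gname}_m{m+1:02d}"
            for j in range(study.images_per_mouse):
                image_id = f"{mouse_id}_i{j+1:02d}"
                scene_seed = int(rng.integers(2**31 - 1))
                image, truth = render_synthetic_image(scene, scene_seed)
                path = outdir / "images" / f"{image_id}.tif"
                imaging.write_image(path, image)
                import tifffile as _tf
                _tf.imwrite(outdir / "images" / f"{image_id}_truth_masks.tif",
                            np.stack([truth.arteriole_wall_mask,
                                      truth.capillary_mask,
                                      truth.abeta_mask]).astype(np.uint8))
                truth_v.append(truth.vessels.assign(image_id=image_id))
                truth_a.append(truth.aggregates.assign(image_id=image_id))
                rows.append({"path": str(path), "group": gname,
                             "mouse_id": mouse_id, "image_id": image_id,
                             "scene_seed": scene_seed})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "images.csv", index=False)
    pd.concat(truth_v, ignore_index=True).to_csv(
        outdir / "truth_vessels.csv", index=False)
    pd.concat(truth_a, ignore_index=True).to_csv(
        outdir / "truth_aggregates.csv", index=False)
    log.info("simulated %d scenes into %s", len(manifest), outdir / "images")
    return manifest


def run_segment_quantify(config: PipelineConfig) -> StudyTable:
    """Segment vessels, detect amyloid, and build the study table."""
    outdir = Path(config.outdir)
    if config.input_images is not None:
        manifest = pd.DataFrame(config.input_images)
    else:
        manifest = _image_manifest(config, outdir)
    seg_params = config.segmentation_params()
    det_params = config.detection_params()
    vessel_parts, agg_parts, vessel_records = [], [], []
    for entry in manifest.itertuples(index=False):
        stack = imaging.read_image(entry.path)
        proj = imaging.max_project(stack)
        arterioles, capillaries = segment_vessels(
            proj.channels, seg_params, proj.pixel_size_um)
        aggregates = detect_amyloid(proj.channels["abeta"], det_params)
        v_rows, a_rows = measure_image(
            entry.group, entry.mouse_id, entry.image_id,
            arterioles, capillaries, aggregates)
        vessel_parts.append(v_rows)
        agg_parts.append(a_rows)
        for vessels in (arterioles, capillaries):
            rec = vessels.records.copy()
            rec.insert(0, "image_id", entry.image_id)
            vessel_records.append(rec)
        (outdir / "masks").mkdir(parents=True, exist_ok=True)
        import tifffile as _tf
        _tf.imwrite(outdir / "masks" / f"{entry.image_id}_labels.tif",
                    np.stack([arterioles.labels, capillaries.labels,
                              aggregates.labels]).astype(np.uint16))
    table = StudyTable(
        vessels=pd.concat(vessel_parts, ignore_index=True),
        aggregates=pd.concat(agg_parts, ignore_index=True),
    )
    table.vessels.to_csv(outdir / "vessels.csv", index=False)
    table.aggregates.to_csv(outdir / "aggregates.csv", index=False)
    pd.concat(vessel_records, ignore_index=True).to_csv(
        outdir / "vessel_objects.csv", index=False)
    log.info("quantified %d vessels, %d aggregates",
             len(table.vessels), len(table.aggregates))
    return table


def _load_table(outdir: Path) -> StudyTable:
    return StudyTable(
        vessels=pd.read_csv(outdir / "vessels.csv"),
        aggregates=pd.read_csv(outdir / "aggregates.csv"),
    )


def run_fit(config: PipelineConfig) -> dict:
    """Preprocess the study table and fit the four group-comparison models."""
    outdir = Path(config.outdir)
    table = _load_table(outdir)
    table, audit = preprocess_study_table(table)
    audit.to_csv(outdir / "outlier_audit.csv", index=False)
    table.exclusions.to_csv(outdir / "exclusions.csv", index=False)
    opts = GLMMOptions(**{"n_restarts": 1, "seed": config.seed,
                          **config.statistics})
    results = {}
    vessels, aggregates = table.vessels, table.aggregates

    analyses = []
    for kind in ("arteriole", "capillary"):
        sub = vessels[vessels["kind"] == kind]
        if len(sub) and sub["group"].nunique() == 2:
            md = ModelData.from_frame(
                sub.assign(value=sub["coverage_pct"] / 100.0), "value")
            analyses.append((f"{kind}_coverage", "zibeta", md))
    for comp in ("intramural", "extramural"):
        sub = aggregates[aggregates["compartment"] == comp]
        sub = sub[sub["size_px"] > 0]
        if len(sub) and sub["group"].nunique() == 2:
            md = ModelData.from_frame(
                sub.assign(value=sub["size_px"].astype(float)), "value")
            analyses.append((f"{comp}_size", "tweedie", md))

    for name, family, md in analyses:
        fit_fun = fit_zib_glmm if family == "zibeta" else fit_tweedie_glmm
        fit = fit_fun(md, opts)
        emm = (estimated_marginal_means(fit) if fit.converged
               else pd.DataFrame(columns=["group", "mean", "ci_low", "ci_high"]))
        results[name] = {
            "family": family,
            "n_obs": fit.n_obs,
            "loglik": fit.loglik,
            "converged": fit.converged,
            "fixed_effects": fit.fixed_effects.to_dict(orient="records"),
            "varcomp": fit.varcomp,
            "emmeans": emm.to_dict(orient="records"),
        }
        log.info("fitted %s (%s): converged=%s", name, family, fit.converged)
    with open(outdir / "fits.json", "w") as fh:
        json.dump(results, fh, indent=2, default=float)
    pd.concat([
        pd.DataFrame(r["fixed_effects"]).assign(analysis=name)
        for name, r in results.items()
    ], ignore_index=True).to_csv(outdir / "fixed_effects.csv", index=False)
    return results


def run_report(config: PipelineConfig) -> list[str]:
    """Emmeans bar charts with 95% CI and per-mouse boxplots of the raw data."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(config.outdir)
    with open(outdir / "fits.json") as fh:
        results = json.load(fh)
    table = _load_table(outdir)
    written = []

    named = [(n, r) for n, r in results.items() if r["emmeans"]]
    if named:
        fig, axes = plt.subplots(1, len(named), figsize=(3.2 * len(named), 3.4))
        axes = np.atleast_1d(axes)
        for ax, (name, r) in zip(axes, named):
            emm = pd.DataFrame(r["emmeans"])
            ax.bar(emm["group"], emm["mean"], color=["#d95f6e", "#5b7fbf"])
            ax.errorbar(emm["group"], emm["mean"],
                        yerr=[emm["mean"] - emm["ci_low"],
                              emm["ci_high"] - emm["mean"]],
                        fmt="none", ecolor="k", capsize=4)
            ax.set_title(name.replace("_", " "))
        fig.tight_layout()
        path = outdir / "emmeans.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(str(path))

    art = table.vessels[table.vessels["kind"] == "arteriole"]
    if len(art):
        mice = sorted(art["mouse_id"].unique())
        fig, axes = plt.subplots(2, max((len(mice) + 1) // 2, 1),
                                 figsize=(2.0 * ((len(mice) + 1) // 2), 5),
                                 sharey=True)
        for ax, mouse in zip(np.ravel(axes), mice):
            sub = art[art["mouse_id"] == mouse]
            ax.boxplot(sub["coverage_pct"], widths=0.5)
            jitter = np.random.default_rng(0).uniform(0.85, 1.15, len(sub))
            ax.plot(jitter, sub["coverage_pct"], ".", alpha=0.5, ms=3)
            ax.set_title(mouse, fontsize=7)
        fig.suptitle("arteriolar amyloid coverage per mouse")
        fig.tight_layout()
        path = outdir / "per_mouse_coverage.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(str(path))
    log.info("report figures: %s", written)
    return written


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the requested stages in order and write a run log.

    Raises before any computation if the configuration is invalid; a stage
    failure aborts with a stage-named diagnostic.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    provenance = {"seed": config.seed, "stages": list(stages),
                  "config": {k: v for k, v in asdict(config).items()}}
    with open(outdir / "run.json", "w") as fh:
        json.dump(provenance, fh, indent=2, default=str)
    out = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        try:
            if stage == "simulate":
                if config.simulation is None:
                    continue
                out["simulate"] = run_simulate(config)
            elif stage == "segment" or stage == "quantify":
                if "table" not in out:
                    out["table"] = run_segment_quantify(config)
            elif stage == "fit":
                out["fits"] = run_fit(config)
            elif stage == "report":
                out["report"] = run_report(config)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
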