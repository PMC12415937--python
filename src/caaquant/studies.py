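"""Simulation studies of the inference machinery.

The recovery study repeatedly simulates tabular data from a known GLMM at
the study's design scale (2 groups x 5 mice x images x units), refits the
model, and summarises the bias of the group-effect estimate, the empirical
coverage of its 95% Wald confidence interval and, under a null effect, the
Wald type-I error rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from scipy import ndimage

from .glmm import (GLMMOptions, ModelData, TweedieParams, ZIBetaParams,
                   fit_tweedie_glmm, fit_zib_glmm)
from .imaging import max_project
from .segmentation import SegmentationParams, segment_vessels
from .simulate import (SceneConfig, render_synthetic_image,
                       simulate_tweedie_dataset, simulate_zib_dataset)


@dataclass
class RecoverySummary:
    """Aggregate of a recovery study for one family."""

    family: str
    n_reps: int
    true_beta1: float
    mean_bias: float
    ci_coverage: float
    rejection_rate: float
    n_converged: int
    fits: pd.DataFrame

    def __str__(self) -> str:
        return (
            f"{self.family}: reps={self.n_reps} (converged {self.n_converged}) "
            f"true beta1={self.true_beta1:+.3f}  mean bias={self.mean_bias:+.4f}  "
            f"95% CI coverage={self.ci_coverage:.3f}  "
            f"reject rate={self.rejection_rate:.3f}"
        )


def run_recovery_study(
    family: str,
    params,
    n_reps: int = 200,
    mice_per_group: int = 5,
    images_per_mouse: int = 5,
    units_per_image: int = 10,
    seed: int = 0,
    options: GLMMOptions | None = None,
) -> RecoverySummary:
    """Simulate-and-refit replications for one response family.

    ``params`` is the generating :class:`ZIBetaParams` (family ``zibeta``)
    or :class:`TweedieParams` (family ``tweedie``); each replicate draws a
    fresh dataset at the given design and refits the matching GLMM with a
    single quasi-Newton start (the moment-based initialisation is reliable
    at this scale).  Coverage counts replicates whose 95% Wald interval for
    the group effect contains the generating value.
    """
    if family not in ("zibeta", "tweedie"):
        raise ValueError(f"unknown family {family!r}")
    simulate = simulate_zib_dataset if family == "zibeta" else simulate_tweedie_dataset
    fit_fun = fit_zib_glmm if family == "zibeta" else fit_tweedie_glmm
    term = "mu_group" if family == "zibeta" else "group"
    options = options or GLMMOptions(n_restarts=1)
    root = np.random.default_rng(seed)
    rows = []
    for rep in range(n_reps):
        rng = np.random.default_rng(root.integers(2**31 - 1))
        frame = simulate(params, mice_per_group, images_per_mouse,
                         units_per_image, rng)
        data = ModelData.from_frame(frame, "value")
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)
            fit = fit_fun(data, replace(options, seed=rep))
        fe = fit.fixed_effects.set_index("term").loc[term]
        est, se, p = float(fe["estimate"]), float(fe["se"]), float(fe["p"])
        rows.append({
            "rep": rep, "beta1_hat": est, "se": se, "p": p,
            "converged": bool(fit.converged),
            "covered": bool(abs(est - params.beta1) <= 1.959963984540054 * se),
            "rejected": bool(p < 0.05),
        })
    fits = pd.DataFrame(rows)
    ok = fits[np.isfinite(fits["se"])]
    return RecoverySummary(
        family=family,
        n_reps=n_reps,
        true_beta1=params.beta1,
        mean_bias=float((ok["beta1_hat"] - params.beta1).mean()),
        ci_coverage=float(ok["covered"].mean()),
        rejection_rate=float(ok["rejected"].mean()),
        n_converged=int(fits["converged"].sum()),
        fits=fits,
    )


def run_segmentation_benchmark(
    n_scenes: int = 20,
    seed: int = 0,
    shape: tuple[int, int] = (320, 320),
) -> dict:
    """Zero-noise segmentation recovery over a suite of synthetic scenes.

    Each scene mixes qualifying arterioles with classifier distractors
    (gap-cut rings, solid disks and sub-threshold complete ringlets) plus
    Collagen-IV-only capillaries.  A truth arteriole counts as recovered if
    a detected arteriole covers at least half of its wall; any detected
    arteriole not matching a truth wall is a distractor false positive.
    Capillary recall is scored the same way on the >= 29-px truth tubes.
    """
    rng = np.random.default_rng(seed)
    params = SegmentationParams()
    totals = {"truth_arterioles": 0, "matched_arterioles": 0,
              "false_positive_arterioles": 0,
              "truth_capillaries": 0, "matched_capillaries": 0,
              "n_scenes": n_scenes}
    for _ in range(n_scenes):
        scene = SceneConfig(
            shape=shape,
            n_arterioles=int(rng.integers(1, 4)),
            n_capillaries=int(rng.integers(3, 7)),
            n_intramural=2, n_extramural=6,
            n_gap_rings=int(rng.integers(1, 3)),
            n_solid_disks=int(rng.integers(0, 3)),
            n_small_rings=int(rng.integers(1, 3)),
            noise_sd=0.0, poisson_scale=0.0, background=0.0,
        )
        image, truth = render_synthetic_image(scene, int(rng.integers(2**31 - 1)))
        proj = max_project(image)
        art, cap = segment_vessels(proj.channels, params, proj.pixel_size_um)

        truth_art, n_art = ndimage.label(truth.arteriole_wall_mask)
        totals["truth_arterioles"] += n_art
        matched_labels = set()
        for lab in range(1, n_art + 1):
            comp = truth_art == lab
            overlap = art.labels[comp]
            hit = overlap[overlap > 0]
            if hit.size >= 0.5 * comp.sum():
                totals["matched_arterioles"] += 1
                matched_labels.update(np.unique(hit).tolist())
        detected_ids = set(art.records["vessel_id"].tolist())
        totals["false_positive_arterioles"] += len(detected_ids - matched_labels)

        truth_cap, n_cap = ndimage.label(truth.capillary_mask)
        for lab in range(1, n_cap + 1):
            comp = truth_cap == lab
            if comp.sum() < params.min_capillary_area_px:
                continue
            totals["truth_capillaries"] += 1
            hit = cap.labels[comp]
            if (hit > 0).sum() >= 0.5 * comp.sum():
                totals["matched_capillaries"] += 1
    totals["arteriole_recall"] = (
        totals["matched_arterioles"] / totals["truth_arterioles"]
        if totals["truth_arterioles"] else float("nan"))
    totals["capillary_recall"] = (
        totals["matched_capillaries"] / totals["truth_capillaries"]
        if totals["truth_capillaries"] else float("nan"))
    return totals
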