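"""Synthetic study generation: tabular draws from the two GLMMs, and rendered
multi-channel confocal scenes with pixel-level ground truth.

The tabular generator draws mouse and image random intercepts from their
Gaussians and responses from the zero-inflated Beta (coverage) and Tweedie
(aggregate size) families at group-specific linear predictors, reproducing
the nested mouse/image/unit hierarchy of the study design (2 groups of 5
mice, ~10 images per mouse).

The image renderer emulates the acquisition: three channels at 0.5676 um/px,
arterioles as annuli positive in both Collagen IV and SMA with an unstained
lumen (outer diameter 10-40 um, wall 2-5 um), capillaries as Collagen-IV-only
curvilinear tubes (~3.5 um wide, smoothed random walks), and amyloid
aggregates as Gaussian blobs whose ground-truth extent is the half-maximum
footprint.  Distractors (gap-rings, solid disks, sub-threshold ringlets) are
available so classifier rejection rules can be exercised.  Noise (Gaussian
background plus photon-like Poisson scaling) is added last; ground truth is
recorded pre-noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as _ndi

from .families import tweedie_rvs
from .glmm import TweedieParams, ZIBetaParams
from .imaging import DEFAULT_PIXEL_SIZE_UM, DEFAULT_Z_STEP_UM, ZStackImage
from .quantify import AGGREGATE_TABLE_COLUMNS, VESSEL_TABLE_COLUMNS, StudyTable

GROUPS = ("control", "clu")

# Default generative parameters, in the vicinity of the fitted effects of
# the study this package emulates (group effect about -0.24 on logit
# coverage, about -0.56 on log intramural size); illustrative, not a
# reproduction of the original data.
DEFAULT_COVERAGE_PARAMS = ZIBetaParams(
    beta0=-2.0, beta1=-0.24, phi=3.0, gamma0=-0.4,
    sigma_mouse=0.35, sigma_image=0.3,
)
DEFAULT_INTRAMURAL_PARAMS = TweedieParams(
    beta0=3.0, beta1=-0.56, phi=2.0, p=1.6,
    sigma_mouse=0.35, sigma_image=0.3,
)
DEFAULT_EXTRAMURAL_PARAMS = TweedieParams(
    beta0=1.6, beta1=-0.48, phi=2.0, p=1.6,
    sigma_mouse=0.35, sigma_image=0.3,
)


@dataclass
class SceneConfig:
    """Geometry and noise of one rendered scene (one image)."""

    shape: tuple[int, int] = (1024, 1024)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    n_z: int = 5
    z_step_um: float = DEFAULT_Z_STEP_UM
    n_arterioles: int = 3
    n_capillaries: int = 8
    n_intramural: int = 6
    n_extramural: int = 30
    arteriole_outer_diameter_um: tuple[float, float] = (12.0, 40.0)
    arteriole_wall_um: tuple[float, float] = (2.0, 5.0)
    capillary_width_um: float = 3.5
    capillary_length_um: tuple[float, float] = (30.0, 120.0)
    aggregate_size_px: tuple[float, float] = (4.0, 80.0)
    n_gap_rings: int = 0
    n_solid_disks: int = 0
    n_small_rings: int = 0
    amplitude: float = 200.0
    background: float = 5.0
    noise_sd: float = 0.0
    poisson_scale: float = 0.0

    def __post_init__(self) -> None:
        if self.arteriole_outer_diameter_um[0] < 10.0:
            raise ValueError("arteriole outer diameter must be >= 10 um")
        for name in ("pixel_size_um", "capillary_width_um", "amplitude"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class StudyConfig:
    """Design and generative parameters of a full synthetic study."""

    groups: tuple[str, str] = GROUPS
    mice_per_group: int = 5
    images_per_mouse: int = 10
    vessels_per_image: int = 10
    aggregates_per_image: int = 10
    coverage: ZIBetaParams = field(
        default_factory=lambda: replace(DEFAULT_COVERAGE_PARAMS))
    intramural: TweedieParams = field(
        default_factory=lambda: replace(DEFAULT_INTRAMURAL_PARAMS))
    extramural: TweedieParams = field(
        default_factory=lambda: replace(DEFAULT_EXTRAMURAL_PARAMS))
    scene: SceneConfig = field(default_factory=SceneConfig)

    def __post_init__(self) -> None:
        if min(self.mice_per_group, self.images_per_mouse,
               self.vessels_per_image) < 1:
            raise ValueError("design counts must be at least 1")


@dataclass
class GroundTruth:
    """Generative truth of a simulated study (tabular side)."""

    coverage: ZIBetaParams
    intramural: TweedieParams
    extramural: TweedieParams
    mouse_effects: pd.DataFrame
    image_effects: pd.DataFrame


# --------------------------------------------------------------------------
# tabular simulation

def _draw_zib(rng, n, eta, params: ZIBetaParams, group):
    gamma1 = params.gamma1 or 0.0
    pi = 1.0 / (1.0 + np.exp(-(params.gamma0 + gamma1 * group)))
    mu = 1.0 / (1.0 + np.exp(-eta))
    zero = rng.random(n) < pi
    a, b = mu * params.phi, (1.0 - mu) * params.phi
    y = rng.beta(np.maximum(a, 1e-12), np.maximum(b, 1e-12))
    y[zero] = 0.0
    return y


def simulate_zib_dataset(
    params: ZIBetaParams,
    mice_per_group: int = 5,
    images_per_mouse: int = 10,
    units_per_image: int = 10,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Draw a coverage dataset exactly from the zero-inflated Beta GLMM.

    Returns a tidy frame (group, mouse_id, image_id, unit_id, value) with
    coverage on the proportion scale.
    """
    rng = np.random.default_rng(rng)
    rows = []
    for g, gname in enumerate(GROUPS):
        for m in range(mice_per_group):
            mouse_id = f"{gname}_m{m+1:02d}"
            u = rng.normal(0.0, params.sigma_mouse)
            for j in range(images_per_mouse):
                image_id = f"{mouse_id}_i{j+1:02d}"
                v = rng.normal(0.0, params.sigma_image)
                eta = params.beta0 + params.beta1 * g + u + v
                y = _draw_zib(rng, units_per_image,
                              np.full(units_per_image, eta), params,
                              np.full(units_per_image, g))
                for k, val in enumerate(y):
                    rows.append({"group": gname, "mouse_id": mouse_id,
                                 "image_id": image_id,
                                 "unit_id": f"{image_id}_u{k+1:03d}",
                                 "value": float(val)})
    return pd.DataFrame(rows)


def simulate_tweedie_dataset(
    params: TweedieParams,
    mice_per_group: int = 5,
    images_per_mouse: int = 10,
    units_per_image: int = 10,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Draw an aggregate-size dataset exactly from the Tweedie GLMM."""
    rng = np.random.default_rng(rng)
    rows = []
    for g, gname in enumerate(GROUPS):
        for m in range(mice_per_group):
            mouse_id = f"{gname}_m{m+1:02d}"
            u = rng.normal(0.0, params.sigma_mouse)
            for j in range(images_per_mouse):
                image_id = f"{mouse_id}_i{j+1:02d}"
                v = rng.normal(0.0, params.sigma_image)
                mu = np.exp(params.beta0 + params.beta1 * g + u + v)
                y = tweedie_rvs(mu, params.phi, params.p,
                                size=units_per_image, rng=rng)
                for k, val in enumerate(y):
                    rows.append({"group": gname, "mouse_id": mouse_id,
                                 "image_id": image_id,
                                 "unit_id": f"{image_id}_u{k+1:03d}",
                                 "value": float(val)})
    return pd.DataFrame(rows)


def simulate_tabular_study(
    config: StudyConfig, seed: int
) -> tuple[StudyTable, GroundTruth]:
    """Simulate a full tabular study from the two generative GLMMs.

    Coverage rows become vessel records (kind ``arteriole``); intramural and
    extramural size rows become aggregate records.  Identical seeds yield
    identical tables.
    """
    rng = np.random.default_rng(seed)
    cov = simulate_zib_dataset(
        config.coverage, config.mice_per_group, config.images_per_mouse,
        config.vessels_per_image, rng)
    intra = simulate_tweedie_dataset(
        config.intramural, config.mice_per_group, config.images_per_mouse,
        config.aggregates_per_image, rng)
    extra = simulate_tweedie_dataset(
        config.extramural, config.mice_per_group, config.images_per_mouse,
        config.aggregates_per_image, rng)

    vessels = cov.rename(columns={"unit_id": "vessel_id"})
    vessels["kind"] = "arteriole"
    vessels["coverage_pct"] = 100.0 * vessels.pop("value")
    vessels["wall_area_px"] = 0
    vessels["abeta_px"] = 0
    vessels = vessels[VESSEL_TABLE_COLUMNS]

    agg_parts = []
    for comp, frame in (("intramural", intra), ("extramural", extra)):
        part = frame.rename(columns={"unit_id": "agg_id"})
        part["compartment"] = comp
        part["size_px"] = part.pop("value")
        part["agg_id"] = part["agg_id"] + "_" + comp[:3]
        agg_parts.append(part[AGGREGATE_TABLE_COLUMNS])
    aggregates = pd.concat(agg_parts, ignore_index=True)

    truth = GroundTruth(
        coverage=config.coverage, intramural=config.intramural,
        extramural=config.extramural,
        mouse_effects=pd.DataFrame(), image_effects=pd.DataFrame(),
    )
    return StudyTable(vessels=vessels, aggregates=aggregates), truth


# --------------------------------------------------------------------------
# scene rendering

@dataclass
class SceneGroundTruth:
    """Pre-noise pixel truth of one rendered scene."""

    arteriole_wall_mask: np.ndarray
    capillary_mask: np.ndarray
    abeta_mask: np.ndarray
    vessels: pd.DataFrame
    aggregates: pd.DataFrame
    config: SceneConfig


def _disk_coords(shape, cy, cx, radius):
    y0 = max(int(np.floor(cy - radius)) - 1, 0)
    y1 = min(int(np.ceil(cy + radius)) + 2, shape[0])
    x0 = max(int(np.floor(cx - radius)) - 1, 0)
    x1 = min(int(np.ceil(cx + radius)) + 2, shape[1])
    yy, xx = np.mgrid[y0:y1, x0:x1]
    return (slice(y0, y1), slice(x0, x1)), yy, xx


def _stamp_annulus(mask, cy, cx, r_in, r_out, gap_angle=None, gap_width=0.0):
    sl, yy, xx = _disk_coords(mask.shape, cy, cx, r_out)
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    ring = (d2 <= r_out**2) & (d2 > r_in**2)
    if gap_angle is not None:
        theta = np.arctan2(yy - cy, xx - cx)
        dth = np.abs(np.angle(np.exp(1j * (theta - gap_angle))))
        ring &= dth > gap_width
    mask[sl] |= ring


def _stamp_disk(mask, cy, cx, radius):
    sl, yy, xx = _disk_coords(mask.shape, cy, cx, radius)
    mask[sl] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def _place_center(rng, shape, margin, occupied, min_dist, tries=200):
    """Rejection-sample a centre at least ``min_dist`` from occupied centres."""
    for _ in range(tries):
        cy = rng.uniform(margin, shape[0] - margin)
        cx = rng.uniform(margin, shape[1] - margin)
        if all((cy - oy) ** 2 + (cx - ox) ** 2 >= (min_dist + od) ** 2
               for oy, ox, od in occupied):
            return cy, cx
    raise RuntimeError("could not place structure without overlap; "
                       "reduce object counts or enlarge the scene")


def _capillary_path(rng, shape, margin, n_steps, step_px):
    """Smoothed random walk with gentle curvature."""
    cy = rng.uniform(margin, shape[0] - margin)
    cx = rng.uniform(margin, shape[1] - margin)
    theta = rng.uniform(0, 2 * np.pi)
    pts = [(cy, cx)]
    for _ in range(n_steps):
        theta += rng.normal(0.0, 0.25)
        cy = np.clip(cy + step_px * np.sin(theta), margin, shape[0] - margin)
        cx = np.clip(cx + step_px * np.cos(theta), margin, shape[1] - margin)
        pts.append((cy, cx))
    return pts


def render_synthetic_image(
    scene: SceneConfig, seed: int
) -> tuple[ZStackImage, SceneGroundTruth]:
    """Render one three-channel scene with pixel-level ground truth.

    Structures are placed without mutual overlap by rejection sampling
    (draw order: arterioles, distractors, capillaries, aggregates); noise is
    applied per z-plane after the truth masks are frozen.
    """
    rng = np.random.default_rng(seed)
    shape = scene.shape
    px = scene.pixel_size_um
    wall_mask = np.zeros(shape, dtype=bool)
    lumen_mask = np.zeros(shape, dtype=bool)
    distract_mask = np.zeros(shape, dtype=bool)
    cap_mask = np.zeros(shape, dtype=bool)
    abeta = np.zeros(shape, dtype=float)
    abeta_mask = np.zeros(shape, dtype=bool)

    occupied: list[tuple[float, float, float]] = []
    vessel_rows = []

    def sample_radii():
        d_out = rng.uniform(*scene.arteriole_outer_diameter_um)
        wall = rng.uniform(*scene.arteriole_wall_um)
        r_out = d_out / 2.0 / px
        r_in = max(r_out - wall / px, 1.0)
        return r_out, r_in

    for i in range(scene.n_arterioles):
        r_out, r_in = sample_radii()
        cy, cx = _place_center(rng, shape, r_out + 6, occupied, r_out + 8)
        before = wall_mask.sum()
        _stamp_annulus(wall_mask, cy, cx, r_in, r_out)
        _stamp_disk(lumen_mask, cy, cx, r_in)
        lumen_mask &= ~wall_mask
        occupied.append((cy, cx, r_out))
        vessel_rows.append({
            "vessel_id": f"art{i+1}", "kind": "arteriole",
            "cy": cy, "cx": cx, "r_out_px": r_out, "r_in_px": r_in,
            "area_px": int(wall_mask.sum() - before),
        })

    for i in range(scene.n_gap_rings):
        r_out, r_in = sample_radii()
        cy, cx = _place_center(rng, shape, r_out + 6, occupied, r_out + 8)
        # cut a gap wide enough to survive rasterisation (>= 3 px arc)
        gap_half = max(0.35, 2.5 / r_in)
        _stamp_annulus(distract_mask, cy, cx, r_in, r_out,
                       gap_angle=rng.uniform(0, 2 * np.pi), gap_width=gap_half)
        occupied.append((cy, cx, r_out))
    for _ in range(scene.n_solid_disks):
        r_out, _ = sample_radii()
        cy, cx = _place_center(rng, shape, r_out + 6, occupied, r_out + 8)
        _stamp_disk(distract_mask, cy, cx, r_out)
        occupied.append((cy, cx, r_out))
    for _ in range(scene.n_small_rings):
        # complete co-positive ring whose wall stays below the 150-px rule
        r_out = rng.uniform(4.0, 5.0)
        r_in = r_out - rng.uniform(1.5, 2.0)
        cy, cx = _place_center(rng, shape, r_out + 6, occupied, r_out + 8)
        _stamp_annulus(distract_mask, cy, cx, r_in, r_out)
        occupied.append((cy, cx, r_out))

    cap_r = scene.capillary_width_um / 2.0 / px
    step_px = max(2.0 * cap_r, 2.0)
    forbidden = wall_mask | distract_mask
    if forbidden.any():
        forbidden = _ndi.binary_dilation(forbidden, iterations=7)
    placed_caps = 0
    for i in range(scene.n_capillaries):
        for _try in range(100):
            length_um = rng.uniform(*scene.capillary_length_um)
            n_steps = max(int(length_um / px / step_px), 3)
            pts = _capillary_path(rng, shape, cap_r + 4, n_steps, step_px)
            cand = np.zeros(shape, dtype=bool)
            for cy, cx in pts:
                _stamp_disk(cand, cy, cx, cap_r)
            if not (cand & (forbidden | cap_mask)).any():
                cap_mask |= cand
                forbidden |= _ndi.binary_dilation(cand, iterations=3)
                placed_caps += 1
                vessel_rows.append({
                    "vessel_id": f"cap{i+1}", "kind": "capillary",
                    "cy": pts[0][0], "cx": pts[0][1], "r_out_px": cap_r,
                    "r_in_px": 0.0, "area_px": int(cand.sum()),
                })
                break

    # amyloid aggregates: Gaussian blobs; truth extent = half-maximum footprint
    agg_rows = []
    wall_idx = np.flatnonzero(wall_mask)
    bg_idx = np.flatnonzero(~(wall_mask | lumen_mask | distract_mask | cap_mask))
    agg_id = 0
    for compartment, count, pool in (
        ("intramural", scene.n_intramural, wall_idx),
        ("extramural", scene.n_extramural, bg_idx),
    ):
        if pool.size == 0:
            continue
        placed: list[tuple[float, float, float]] = []
        for _ in range(count):
            agg_id += 1
            target_px = rng.uniform(*scene.aggregate_size_px)
            r_half = np.sqrt(target_px / np.pi)
            sigma = r_half / np.sqrt(2.0 * np.log(2.0))
            cy = cx = None
            for _try in range(100):  # keep half-max footprints disjoint
                flat = int(pool[rng.integers(pool.size)])
                ty, tx = np.unravel_index(flat, shape)
                if all((ty - oy) ** 2 + (tx - ox) ** 2
                       >= (r_half + orad + 2.0) ** 2
                       for oy, ox, orad in placed):
                    cy, cx = int(ty), int(tx)
                    break
            if cy is None:
                agg_id -= 1
                continue
            placed.append((cy, cx, r_half))
            sl, yy, xx = _disk_coords(shape, cy, cx, 4.0 * sigma)
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            blob = scene.amplitude * np.exp(-d2 / (2.0 * sigma**2))
            abeta[sl] = np.maximum(abeta[sl], blob)
            extent = d2 <= r_half**2
            abeta_mask[sl] |= extent
            agg_rows.append({
                "agg_id": f"agg{agg_id}", "compartment": compartment,
                "cy": float(cy), "cx": float(cx),
                "size_px": int(extent.sum()),
            })

    col = np.zeros(shape, dtype=float)
    sma = np.zeros(shape, dtype=float)
    col[wall_mask | cap_mask | distract_mask] = scene.amplitude
    sma[wall_mask | distract_mask] = scene.amplitude

    # distribute into z-planes with a triangular axial profile peaking at 1,
    # so the pre-noise maximum projection equals the 2-D scene exactly
    n_z = scene.n_z
    zc = (n_z - 1) / 2.0
    weights = 1.0 - 0.5 * np.abs(np.arange(n_z) - zc) / max(zc, 1.0)
    channels = {}
    for name, plane in (("collagen4", col), ("sma", sma), ("abeta", abeta)):
        stack = plane[np.newaxis] * weights[:, np.newaxis, np.newaxis]
        stack = stack + scene.background
        if scene.poisson_scale > 0:
            stack = rng.poisson(stack * scene.poisson_scale) / scene.poisson_scale
        if scene.noise_sd > 0:
            stack = stack + rng.normal(0.0, scene.noise_sd, stack.shape)
        channels[name] = np.clip(stack, 0.0, None)

    image = ZStackImage(channels=channels, pixel_size_um=px,
                        z_step_um=scene.z_step_um)
    truth = SceneGroundTruth(
        arteriole_wall_mask=wall_mask, capillary_mask=cap_mask,
        abeta_mask=abeta_mask,
        vessels=pd.DataFrame(vessel_rows, columns=[
            "vessel_id", "kind", "cy", "cx", "r_out_px", "r_in_px", "area_px"]),
        aggregates=pd.DataFrame(agg_rows, columns=[
            "agg_id", "compartment", "cy", "cx", "size_px"]),
        config=scene,
    )
    return image, truth
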