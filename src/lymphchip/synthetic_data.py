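"""Synthetic inputs with known ground truth for every pipeline stage.

The study's raw data are fluorescence micrographs and assay plates; this
module emulates them so the quantification stack can be exercised and
validated end to end without any downloads:

- elliptical cell masks with controlled aspect ratio and von Mises
  distributed orientations (immunofluorescence morphometry stand-in),
- sprout-front masks: interface-connected fingers with a directional
  bias plus disconnected blobs emulating single-cell migration,
- intensity images/line profiles rendered from transport solutions,
  sampled every 3 h with additive Gaussian noise,
- Ct tables with specified fold changes and OD plates generated from
  known 4PL parameters.

Every generator is a pure function of (parameters, seed): numpy's
``default_rng`` with an explicit seed, recorded in the returned
:class:`GroundTruth` manifest.  Mask noise flips boundary pixels only,
mimicking segmentation jitter without breaking connectivity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk, ellipse as draw_ellipse
from skimage.morphology import binary_dilation, binary_erosion

from .assays import logistic4
from .device_model import ValidationError
from .solute_transport import ConcentrationField

__all__ = [
    "GroundTruth",
    "gen_ellipse_masks",
    "gen_sprout_field",
    "gen_intensity_series",
    "gen_ct_table",
    "gen_elisa_plate",
]


@dataclass(frozen=True)
class GroundTruth:
    """Manifest of true parameters behind a generated artifact."""

    generator: str
    seed: int
    params: dict = field(default_factory=dict)
    files: tuple[str, ...] = ()

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)!r}")


# --------------------------------------------------------------------------
# cell masks


def _axial_von_mises(rng, mu_deg: float, kappa: float, n: int) -> np.ndarray:
    """Axial (180-deg periodic) von Mises sample in degrees, [-90, 90)."""
    if kappa < 0:
        raise ValidationError("kappa must be >= 0")
    if kappa == 0:
        return rng.uniform(-90.0, 90.0, size=n)
    doubled = rng.vonmises(np.deg2rad(2.0 * mu_deg), kappa, size=n)
    ang = np.rad2deg(doubled) / 2.0
    return (ang + 90.0) % 180.0 - 90.0


def _flip_boundary(rng, mask: np.ndarray, rate: float) -> np.ndarray:
    """Flip a fraction of boundary pixels (in and out) of a binary mask."""
    if rate <= 0:
        return mask
    inner = mask & ~binary_erosion(mask)
    outer = binary_dilation(mask) & ~mask
    out = mask.copy()
    for band, new in ((inner, False), (outer, True)):
        idx = np.flatnonzero(band)
        k = int(round(rate * idx.size))
        if k:
            chosen = rng.choice(idx, size=k, replace=False)
            out.flat[chosen] = new
    return out


def gen_ellipse_masks(
    n: int,
    ar_range: tuple[float, float] = (1.0, 10.0),
    orientation_mu: float = 0.0,
    orientation_kappa: float = 0.0,
    size_range: tuple[float, float] = (15.0, 30.0),
    noise: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (1024, 1024),
    max_retries: int = 200,
) -> tuple[np.ndarray, GroundTruth]:
    """Labeled mask of ``n`` non-overlapping ellipses with known truth.

    ``ar_range`` bounds the aspect ratio (uniform draw, within [1, 20]),
    ``size_range`` the minor semi-axis in pixels, and orientations
    follow an axial von Mises law (kappa = 0: uniform).  ``noise`` is
    the boundary-pixel flip rate.  The manifest records per-object true
    aspect ratio, area, orientation and center.
    """
    if not (1.0 <= ar_range[0] <= ar_range[1] <= 20.0):
        raise ValidationError("ar_range must lie within [1, 20]")
    rng = np.random.default_rng(seed)
    ars = rng.uniform(ar_range[0], ar_range[1], size=n)
    minors = rng.uniform(size_range[0], size_range[1], size=n)
    angles = _axial_von_mises(rng, orientation_mu, orientation_kappa, n)

    lab = np.zeros(shape, dtype=np.int32)
    records = []
    h, w = shape
    # place large objects first: rejection sampling packs far better that way
    order = np.argsort(-(ars * minors**2))
    for i in order:
        b = minors[i]
        a = b * ars[i]
        margin = int(math.ceil(a)) + 2
        if 2 * margin >= min(h, w):
            raise ValidationError(
                f"object {i} (major semi-axis {a:.0f} px) does not fit a {shape} canvas"
            )
        placed = False
        for _ in range(max_retries):
            cy = rng.integers(margin, h - margin)
            cx = rng.integers(margin, w - margin)
            rr, cc = draw_ellipse(cy, cx, b, a, shape=shape, rotation=np.deg2rad(angles[i]))
            if np.any(lab[rr, cc]):
                continue
            obj = np.zeros(shape, dtype=bool)
            obj[rr, cc] = True
            if noise > 0:
                obj = _flip_boundary(rng, obj, noise)
                obj[lab > 0] = False
            lab[obj] = i + 1
            records.append(
                {
                    "label": int(i) + 1,
                    "aspect_ratio": float(ars[i]),
                    "minor_semiaxis": float(b),
                    "major_semiaxis": float(a),
                    "orientation": float(angles[i]),
                    "area": math.pi * a * b,
                    "center": (int(cx), int(cy)),
                }
            )
            placed = True
            break
        if not placed:
            raise ValidationError(
                f"could not place object {i} without overlap after {max_retries} retries; "
                "reduce n or object size"
            )
    truth = GroundTruth(
        generator="gen_ellipse_masks",
        seed=seed,
        params={
            "n": n,
            "ar_range": ar_range,
            "orientation_mu": orientation_mu,
            "orientation_kappa": orientation_kappa,
            "size_range": size_range,
            "noise": noise,
            "shape": shape,
            "objects": records,
        },
    )
    return lab, truth


# --------------------------------------------------------------------------
# sprout fields


def gen_sprout_field(
    n_sprouts: int,
    distance_range: tuple[float, float] = (100.0, 400.0),
    direction_kappa: float = 4.0,
    single_cell_fraction: float = 0.0,
    width_range: tuple[float, float] = (12.0, 24.0),
    seed: int = 0,
    shape: tuple[int, int] = (512, 768),
    interface_position: int = 10,
    pixel_size: float = 1.0,
) -> tuple[np.ndarray, GroundTruth]:
    """Binary gel mask with interface-connected sprout fingers.

    Fingers start at the interface column and extend their drawn
    distance (pixels) into the gel at a von Mises-distributed angle
    about the interface normal (+x); ``single_cell_fraction`` of
    additional disconnected blobs are placed deep in the gel, emulating
    single-cell migration events that the sprout-distance quantification
    must exclude.  Truth records each structure's class, distance (the
    perpendicular extent) and direction.
    """
    if n_sprouts < 0:
        raise ValidationError("n_sprouts must be >= 0")
    rng = np.random.default_rng(seed)
    h, w = shape
    mask = np.zeros(shape, dtype=bool)

    records = []
    lanes = np.linspace(40, h - 40, max(n_sprouts, 1))
    drift_factor = 0.2  # lateral drift per unit advance, scaled by tan(angle)
    for i in range(n_sprouts):
        dist = float(rng.uniform(*distance_range))
        angle = float(rng.vonmises(0.0, direction_kappa)) if direction_kappa > 0 else float(
            rng.uniform(-0.9, 0.9)
        )
        angle = float(np.clip(angle, -0.9, 0.9))
        width = float(rng.uniform(*width_range))
        y0 = float(lanes[i])
        # draw the finger column by column: max extent is exactly round(dist) px
        dist_px = max(int(round(dist)), 1)
        for k in range(dist_px + 1):
            s = k / dist_px
            x = interface_position + k
            if x >= w:
                break
            y = y0 - math.tan(angle) * k * drift_factor
            half = max(width * (1.0 - 0.6 * s) / 2.0, 1.0)
            y = float(np.clip(y, half + 1.0, h - half - 2.0))  # keep the finger on-canvas
            r0 = max(int(round(y - half)), 0)
            r1 = min(int(round(y + half)) + 1, h)
            mask[r0:r1, x] = True
        records.append(
            {
                "kind": "sprout",
                "distance": float(dist_px),
                "drawn_direction_deg": math.degrees(math.atan(drift_factor * math.tan(angle))),
                "sampled_direction_deg": math.degrees(angle),
                "width": width,
                "y0": y0,
            }
        )

    n_single = int(round(single_cell_fraction * n_sprouts))
    for j in range(n_single):
        x = rng.uniform(interface_position + distance_range[1] + 60, w - 30)
        y = rng.uniform(30, h - 30)
        r = rng.uniform(6, 12)
        rr, cc = draw_disk((y, x), r, shape=shape)
        mask[rr, cc] = True
        records.append({"kind": "single_cell", "x": float(x), "y": float(y), "radius": float(r)})

    truth = GroundTruth(
        generator="gen_sprout_field",
        seed=seed,
        params={
            "n_sprouts": n_sprouts,
            "distance_range": distance_range,
            "direction_kappa": direction_kappa,
            "single_cell_fraction": single_cell_fraction,
            "interface_position": interface_position,
            "pixel_size": pixel_size,
            "shape": shape,
            "structures": records,
        },
    )
    return mask, truth


# --------------------------------------------------------------------------
# intensity images


def gen_intensity_series(
    solution: ConcentrationField,
    sampling_interval: float = 10800.0,
    noise_sigma: float = 0.0,
    pixel_size: float = 10e-6,
    image_height: int = 64,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render a transport solution as a fluorescence image time series.

    Each frame is the 1D concentration profile at one sampled time,
    constant across the transverse (row) axis, resampled onto a uniform
    pixel grid of spacing ``pixel_size``, plus additive Gaussian noise
    of standard deviation ``noise_sigma`` (intensity units).  Sampling
    every 3 h (default) over a 24-h solution yields 9 frames.

    Returns ``(times, stack, truth)`` with ``stack`` of shape
    (n_frames, image_height, n_columns).
    """
    if noise_sigma < 0:
        raise ValidationError("noise_sigma must be >= 0")
    t_max = float(solution.times[np.isfinite(solution.times)].max())
    sample_times = np.arange(0.0, t_max + 0.5 * sampling_interval, sampling_interval)
    if sample_times.size == 0 or sample_times[-1] > t_max + 1e-9:
        raise ValidationError("solution does not cover the requested sampling times")

    length = float(solution.x[-1] + (solution.x[-1] - solution.x[-2]) / 2.0)
    n_cols = max(int(round(length / pixel_size)), 2)
    xs = (np.arange(n_cols) + 0.5) * pixel_size

    rng = np.random.default_rng(seed)
    frames = []
    for t in sample_times:
        profile = np.interp(xs, solution.x, solution.at(t))
        img = np.tile(profile, (image_height, 1))
        if noise_sigma > 0:
            img = img + rng.normal(0.0, noise_sigma, size=img.shape)
        frames.append(img)
    stack = np.asarray(frames)
    truth = GroundTruth(
        generator="gen_intensity_series",
        seed=seed,
        params={
            "sampling_interval": sampling_interval,
            "noise_sigma": noise_sigma,
            "pixel_size": pixel_size,
            "image_height": image_height,
            "n_frames": int(stack.shape[0]),
            "times": sample_times,
        },
    )
    return sample_times, stack, truth


# --------------------------------------------------------------------------
# assay tables


def gen_ct_table(
    genes,
    groups,
    true_folds: dict,
    ct_sd: float = 0.0,
    n_replicates: int = 3,
    baseline_ct: float = 22.0,
    housekeeping: str = "GAPDH",
    housekeeping_ct: float = 15.0,
    control_group: str = "control",
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Ct table realizing specified fold changes.

    ``true_folds[(gene, group)]`` (or ``true_folds[gene][group]``) gives
    the fold change vs. the control group; unspecified entries default
    to 1.  Target Ct = baseline - log2(fold) + noise; housekeeping Ct is
    constant + noise.  With ``ct_sd = 0`` the comparative-Ct analysis
    returns the folds exactly.
    """
    if ct_sd < 0:
        raise ValidationError("ct_sd must be >= 0")

    def fold_for(gene, group):
        if group == control_group:
            return 1.0
        if (gene, group) in true_folds:
            f = true_folds[(gene, group)]
        elif gene in true_folds and isinstance(true_folds[gene], dict):
            f = true_folds[gene].get(group, 1.0)
        else:
            f = 1.0
        if not f > 0:
            raise ValidationError(f"fold for ({gene}, {group}) must be > 0, got {f!r}")
        return float(f)

    rng = np.random.default_rng(seed)
    rows = []
    for group in groups:
        for rep in range(1, n_replicates + 1):
            sample = f"{group}_r{rep}"
            rows.append(
                {
                    "sample_id": sample,
                    "group": group,
                    "gene": housekeeping,
                    "replicate": rep,
                    "ct": housekeeping_ct + (rng.normal(0, ct_sd) if ct_sd else 0.0),
                }
            )
            for gene in genes:
                ct = baseline_ct - math.log2(fold_for(gene, group))
                rows.append(
                    {
                        "sample_id": sample,
                        "group": group,
                        "gene": gene,
                        "replicate": rep,
                        "ct": ct + (rng.normal(0, ct_sd) if ct_sd else 0.0),
                    }
                )
    table = pd.DataFrame(rows)
    truth = GroundTruth(
        generator="gen_ct_table",
        seed=seed,
        params={
            "genes": list(genes),
            "groups": list(groups),
            "folds": {f"{g}|{gr}": fold_for(g, gr) for g in genes for gr in groups},
            "ct_sd": ct_sd,
            "n_replicates": n_replicates,
            "housekeeping": housekeeping,
            "control_group": control_group,
        },
    )
    return table, truth


def gen_elisa_plate(
    params: tuple[float, float, float, float] = (0.05, 2.4, 150.0, 1.2),
    concentrations=None,
    od_sd: float = 0.0,
    n_replicates: int = 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """OD plate generated from known 4PL parameters (a, d, c, b).

    Default standards: a 2-fold dilution series spanning the inflection.
    Returns a tidy frame (concentration, replicate, od).
    """
    if od_sd < 0:
        raise ValidationError("od_sd must be >= 0")
    a, d, c, b = params
    if concentrations is None:
        concentrations = c * 2.0 ** np.arange(-4, 4)  # 8 standards around EC50
    conc = np.asarray(list(concentrations), dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for x in conc:
        y0 = float(logistic4(x, a, d, c, b))
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "concentration": float(x),
                    "replicate": rep,
                    "od": y0 + (rng.normal(0, od_sd) if od_sd else 0.0),
                }
            )
    plate = pd.DataFrame(rows)
    truth = GroundTruth(
        generator="gen_elisa_plate",
        seed=seed,
        params={"a": a, "d": d, "c": c, "b": b, "od_sd": od_sd,
                "concentrations": conc, "n_replicates": n_replicates},
    )
    return plate, truth
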