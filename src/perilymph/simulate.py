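"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here at desk scale:

* tubular vessel masks and radially decaying intensity fields around them
  (the perilymphatic gradient, modelled as ``b + A·exp(-d/λ)`` plus
  Gaussian noise on top of an isotype-level background ``b``);
* persistent random-walk cell tracks with a tunable directional bias
  toward the +y stimulus axis;
* 3-D cell centroids placed at known positions relative to a vessel lumen
  (interstitial / adherent / luminal);
* single-cell tables with marker-positive and -negative populations split
  across lymph-node compartments, together with the marker-negative
  reference sets used to derive gates.

All generators are deterministic for a given seed; every random draw in
one call flows from a single seeded generator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import ImageStack, Track, VesselMask

__all__ = [
    "TubeSpec",
    "GradientFieldParams",
    "WalkParams",
    "LNTableParams",
    "make_vessel_mask",
    "make_gradient_image",
    "make_tracks",
    "make_dc_points",
    "make_ln_cell_table",
    "make_gradient_study",
]

logger = logging.getLogger(__name__)


def _rng(seed=None, rng=None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# vessel masks


@dataclass
class TubeSpec:
    """A tubular vessel: all points within ``radius_um`` of a polyline.

    ``control_points`` are physical µm coordinates in image axis order
    (``(y, x)`` rows for 2-D, ``(z, y, x)`` for 3-D).
    """

    control_points: np.ndarray
    radius_um: float

    def __post_init__(self) -> None:
        self.control_points = np.atleast_2d(np.asarray(self.control_points, dtype=float))
        self.radius_um = float(self.radius_um)


def _polyline_distance(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Min distance from each point to a polyline (physical coordinates)."""
    dmin = np.full(len(points), np.inf)
    if len(polyline) == 1:
        return np.linalg.norm(points - polyline[0], axis=1)
    for p0, p1 in zip(polyline[:-1], polyline[1:]):
        v = p1 - p0
        l2 = float(v @ v)
        if l2 == 0:
            d = np.linalg.norm(points - p0, axis=1)
        else:
            t = np.clip((points - p0) @ v / l2, 0.0, 1.0)
            proj = p0 + t[:, None] * v
            d = np.linalg.norm(points - proj, axis=1)
        np.minimum(dmin, d, out=dmin)
    return dmin


def make_vessel_mask(
    image_shape,
    pixel_size,
    geometry="random",
    seed=None,
    rng: np.random.Generator | None = None,
) -> VesselMask:
    """Rasterize a tubular vessel into a binary mask.

    ``geometry`` is a :class:`TubeSpec` or ``"random"`` for a wiggly tube
    running the length of the y axis. A voxel belongs to the vessel when
    its centre lies within the tube radius of the centerline, measured in
    anisotropy-scaled physical distance.
    """
    shape = tuple(int(n) for n in image_shape)
    ndim = len(shape)
    if ndim not in (2, 3):
        raise ValueError("image_shape must be 2-D or 3-D")
    spacing = tuple(float(s) for s in np.broadcast_to(np.atleast_1d(pixel_size), (ndim,)))

    if geometry == "random":
        gen = _rng(seed, rng)
        y_ax = ndim - 2  # tube runs along y
        extent = [(n - 1) * s for n, s in zip(shape, spacing)]
        n_ctrl = max(3, shape[y_ax] // 8)
        ys = np.linspace(0, extent[y_ax], n_ctrl)
        pts = np.empty((n_ctrl, ndim))
        pts[:, y_ax] = ys
        for ax in range(ndim):
            if ax == y_ax:
                continue
            wiggle = np.cumsum(gen.normal(0, extent[ax] * 0.02, n_ctrl))
            pts[:, ax] = extent[ax] / 2 + wiggle - wiggle.mean()
        radius = float(gen.uniform(2.0, 5.0))
        geometry = TubeSpec(control_points=pts, radius_um=radius)
    if not isinstance(geometry, TubeSpec):
        raise TypeError("geometry must be a TubeSpec or 'random'")
    if geometry.control_points.shape[1] != ndim:
        raise ValueError("tube control points must match image dimensionality")
    if geometry.radius_um < min(spacing):
        raise ValueError(
            f"tube radius {geometry.radius_um} µm is below one pixel "
            f"(min spacing {min(spacing)} µm): raise the radius or refine the grid"
        )

    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, ndim)
    d = _polyline_distance(grid, geometry.control_points)
    mask = (d <= geometry.radius_um + 1e-9).reshape(shape)
    if not mask.any():
        raise ValueError("tube rasterized to an empty mask; check geometry vs image extent")
    return VesselMask(data=mask, spacing=spacing)


# ---------------------------------------------------------------------------
# gradient images


@dataclass
class GradientFieldParams:
    """Parameters of the synthetic perilymphatic intensity field.

    ``I(pixel) = background + amplitude · exp(-d/decay_length) + ε`` with
    ``ε ~ N(0, noise_sd²)``, where ``d`` is the physical distance (µm) to
    the nearest vessel pixel (0 on the vessel). Intensities are clipped at
    zero — fluorescence cannot be negative. ``background`` models the
    isotype-staining floor.
    """

    amplitude: float = 1000.0
    background: float = 100.0
    decay_length_um: float = 15.0
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.background < 0 or self.noise_sd < 0:
            raise ValueError("amplitude, background and noise_sd must be >= 0")
        if self.decay_length_um <= 0:
            raise ValueError("decay_length_um must be > 0")


def make_gradient_image(
    mask: VesselMask,
    params: GradientFieldParams,
    rng: np.random.Generator | None = None,
    channel: str = "chemokine",
) -> ImageStack:
    """Synthesize a noisy exponentially decaying field around a vessel mask."""
    if mask.n_vessel_pixels == 0:
        raise ValueError("vessel mask is empty")
    d = ndimage.distance_transform_edt(~mask.data, sampling=mask.spacing)
    img = params.background + params.amplitude * np.exp(-d / params.decay_length_um)
    if params.noise_sd > 0:
        gen = _rng(params.seed, rng)
        img = img + gen.normal(0.0, params.noise_sd, size=img.shape)
    n_clipped = int((img < 0).sum())
    if n_clipped:
        logger.info(
            "make_gradient_image: clipped %d/%d pixels (%.3f%%) at zero",
            n_clipped,
            img.size,
            100 * n_clipped / img.size,
        )
    return ImageStack(data=np.clip(img, 0.0, None), spacing=mask.spacing, channel=channel)


# ---------------------------------------------------------------------------
# random-walk tracks


@dataclass
class WalkParams:
    """Persistent biased random walk emulating migrating dendritic cells.

    Per step the heading is a persistence-weighted mixture of the previous
    heading and a fresh direction draw; with probability ``bias`` the draw
    is resampled until it points toward the attractant (+y, sign
    configurable), which leaves the speed distribution independent of the
    bias. Step length is ``speed · dt`` with speed drawn per step from a
    normal clipped at zero.

    Defaults mimic dendritic cells crawling at ~6 µm/min recorded every
    30 s for 30 min.
    """

    n_tracks: int = 50
    n_steps: int = 61
    dt_s: float = 30.0
    step_speed_mean: float = 0.1  # µm/s
    step_speed_sd: float = 0.03
    persistence: float = 0.5
    bias: float = 0.0
    bias_sign: int = 1
    ndim: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be > 0")
        if self.step_speed_mean < 0 or self.step_speed_sd < 0:
            raise ValueError("speeds must be >= 0")
        if not 0 <= self.persistence < 1:
            raise ValueError("persistence must be in [0, 1)")
        if not 0 <= self.bias <= 1:
            raise ValueError("bias must be in [0, 1]")
        if self.ndim not in (2, 3):
            raise ValueError("ndim must be 2 or 3")


_Y = 1  # index of the stimulus axis in (x, y[, z]) coordinates


def _unit_direction(gen: np.random.Generator, ndim: int) -> np.ndarray:
    v = gen.normal(size=ndim)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover - vanishing probability
        v = gen.normal(size=ndim)
        n = np.linalg.norm(v)
    return v / n


def make_tracks(params: WalkParams, assay: str = "", rng=None) -> list[Track]:
    """Simulate a cohort of persistent (optionally biased) random walks."""
    gen = _rng(params.seed, rng)
    tracks = []
    t = np.arange(params.n_steps) * params.dt_s
    for i in range(params.n_tracks):
        pos = np.zeros((params.n_steps, params.ndim))
        heading = None
        for k in range(1, params.n_steps):
            draw = _unit_direction(gen, params.ndim)
            if params.bias > 0 and gen.random() < params.bias:
                while params.bias_sign * draw[_Y] <= 0:
                    draw = _unit_direction(gen, params.ndim)
            if heading is None:
                heading = draw
            else:
                mixed = params.persistence * heading + (1 - params.persistence) * draw
                n = np.linalg.norm(mixed)
                heading = mixed / n if n > 1e-12 else draw
            speed = params.step_speed_mean
            if params.step_speed_sd > 0:
                speed = max(0.0, gen.normal(params.step_speed_mean, params.step_speed_sd))
            pos[k] = pos[k - 1] + heading * speed * params.dt_s
        tracks.append(
            Track(track_id=f"track_{i:04d}", t=t.copy(), positions=pos, assay=assay)
        )
    return tracks


# ---------------------------------------------------------------------------
# 3-D cell centroids around a vessel


CLASS_NAMES = {1: "interstitial", 2: "adherent", 3: "luminal"}


def make_dc_points(
    mask3d: VesselMask,
    counts: dict[str, int],
    d_adh: float = 5.0,
    margin: float = 1.0,
    seed=None,
    rng=None,
) -> pd.DataFrame:
    """Place labelled cell centroids at known positions relative to a vessel.

    ``counts`` gives the number of points per class (``interstitial``,
    ``adherent``, ``luminal``). Luminal points sit on vessel voxels;
    adherent points outside the vessel at surface distance within
    ``(margin, d_adh - margin)``; interstitial points farther than
    ``d_adh + margin``. The margins keep every point away from a class
    boundary so downstream classification must agree with the ground
    truth. Points are voxel centres, returned in physical µm with columns
    ``x_um, y_um, z_um`` and the ``true_class`` code (1/2/3).
    """
    if mask3d.data.ndim != 3:
        raise ValueError("make_dc_points needs a 3-D mask")
    if margin <= 0:
        raise ValueError("margin must be > 0")
    wanted = {k: int(counts.get(k, 0)) for k in ("interstitial", "adherent", "luminal")}
    if any(v < 0 for v in wanted.values()):
        raise ValueError("counts must be >= 0")
    if wanted["adherent"] > 0 and margin >= d_adh / 2:
        raise ValueError(
            f"adherence band (margin, d_adh - margin) is empty for margin={margin}, "
            f"d_adh={d_adh}"
        )
    gen = _rng(seed, rng)
    outside = ndimage.distance_transform_edt(~mask3d.data, sampling=mask3d.spacing)
    regions = {
        "luminal": mask3d.data,
        "adherent": (~mask3d.data) & (outside > margin) & (outside < d_adh - margin),
        "interstitial": outside > d_adh + margin,
    }
    rows = []
    spacing = np.asarray(mask3d.spacing)
    cid = 0
    for name in ("interstitial", "adherent", "luminal"):
        n = wanted[name]
        if n == 0:
            continue
        idx = np.argwhere(regions[name])
        if len(idx) == 0:
            raise ValueError(f"no voxel available for class {name!r} at these parameters")
        if len(idx) < n:
            raise ValueError(
                f"class {name!r}: requested {n} points but only {len(idx)} voxels qualify"
            )
        chosen = idx[gen.choice(len(idx), size=n, replace=False)]
        coords = chosen * spacing  # (z, y, x) µm
        code = {"interstitial": 1, "adherent": 2, "luminal": 3}[name]
        for z, y, x in coords:
            rows.append(
                {
                    "cell_id": f"cell_{cid:04d}",
                    "x_um": x,
                    "y_um": y,
                    "z_um": z,
                    "true_class": code,
                }
            )
            cid += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# lymph-node single-cell tables


@dataclass
class LNTableParams:
    """Synthetic lymph-node single-cell table.

    Emulates the exported per-cell measurement tables of a segmented LN
    section: every cell carries a compartment label (SCS or parenchyma), a
    nuclear area and per-marker intensities drawn from its ground-truth
    positive or negative distribution. Marker positivity is nested the way
    the biology is: hapten-labelled (FITC⁺) migratory cells are a subset
    of the CD11c⁺ dendritic cells, so ``frac_fitc_*`` is the FITC⁺
    fraction *within* CD11c⁺ cells of that compartment. Positive counts
    are deterministic (``round(frac · n)``) so ground-truth ratios are
    exact. ``frac_debris`` cells are segmentation junk: dim DAPI,
    implausibly small area, no marker signal.

    ``intensity`` maps marker -> (neg_mean, neg_sd, pos_mean, pos_sd).
    """

    n_scs: int = 300
    n_parenchyma: int = 700
    frac_cd11c_scs: float = 0.30
    frac_cd11c_par: float = 0.20
    frac_fitc_scs: float = 0.50
    frac_fitc_par: float = 0.25
    frac_debris: float = 0.05
    intensity: dict = field(
        default_factory=lambda: {
            "DAPI": (50.0, 15.0, 500.0, 100.0),
            "CD11c": (30.0, 10.0, 300.0, 60.0),
            "FITC": (20.0, 8.0, 250.0, 50.0),
        }
    )
    area_mean_um2: float = 45.0
    area_sd_um2: float = 8.0
    n_reference: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        for f in (
            self.frac_cd11c_scs,
            self.frac_cd11c_par,
            self.frac_fitc_scs,
            self.frac_fitc_par,
            self.frac_debris,
        ):
            if not 0 <= f <= 1:
                raise ValueError("fractions must be in [0, 1]")
        for marker, (nm, ns, pm, ps) in self.intensity.items():
            if ns < 0 or ps < 0:
                raise ValueError(f"negative sd for marker {marker}")


def _draw(gen, mean, sd, n):
    return np.clip(gen.normal(mean, sd, size=n), 0.0, None)


def make_ln_cell_table(
    params: LNTableParams, rng=None
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Generate (cell table, marker-negative reference sets).

    The reference sets are independent draws from each marker's negative
    distribution — they stand in for cells measured in marker-negative
    tissue areas and are what gates are derived from.
    """
    gen = _rng(params.seed, rng)
    rows = []
    cid = 0
    for comp, n, f_cd11c, f_fitc in (
        ("SCS", params.n_scs, params.frac_cd11c_scs, params.frac_fitc_scs),
        ("parenchyma", params.n_parenchyma, params.frac_cd11c_par, params.frac_fitc_par),
    ):
        n_debris = int(round(params.frac_debris * n))
        n_real = n - n_debris
        n_cd11c = int(round(f_cd11c * n_real))
        n_fitc = int(round(f_fitc * n_cd11c))
        # assign ground-truth status by shuffled slot
        cd11c_flags = np.zeros(n_real, dtype=bool)
        fitc_flags = np.zeros(n_real, dtype=bool)
        order = gen.permutation(n_real)
        cd11c_idx = order[:n_cd11c]
        cd11c_flags[cd11c_idx] = True
        fitc_flags[cd11c_idx[gen.permutation(n_cd11c)[:n_fitc]]] = True
        valid_flags = np.concatenate([np.ones(n_real, bool), np.zeros(n_debris, bool)])
        cd11c_flags = np.concatenate([cd11c_flags, np.zeros(n_debris, bool)])
        fitc_flags = np.concatenate([fitc_flags, np.zeros(n_debris, bool)])

        n_tot = n_real + n_debris
        x = gen.uniform(0, 500, n_tot)
        y = gen.uniform(0, 500, n_tot)
        area = _draw(gen, params.area_mean_um2, params.area_sd_um2, n_tot)
        area[~valid_flags] = gen.uniform(1.0, 8.0, n_debris)

        intens = {}
        for marker, (nm, ns, pm, ps) in params.intensity.items():
            if marker == "DAPI":
                pos = valid_flags
            elif marker == "CD11c":
                pos = cd11c_flags
            else:
                pos = fitc_flags
            v = _draw(gen, nm, ns, n_tot)
            v[pos] = _draw(gen, pm, ps, int(pos.sum()))
            intens[marker] = v

        for i in range(n_tot):
            rows.append(
                {
                    "cell_id": f"cell_{cid:05d}",
                    "x_um": x[i],
                    "y_um": y[i],
                    "compartment": comp,
                    "area_um2": area[i],
                    **{f"int_{m}": intens[m][i] for m in params.intensity},
                    "truth_valid": bool(valid_flags[i]),
                    "truth_cd11c": bool(cd11c_flags[i]),
                    "truth_fitc": bool(fitc_flags[i]),
                }
            )
            cid += 1
    cells = pd.DataFrame(rows)
    negatives = {
        marker: _draw(gen, nm, ns, params.n_reference)
        for marker, (nm, ns, _, _) in params.intensity.items()
    }
    return cells, negatives


# ---------------------------------------------------------------------------
# two-condition gradient study


def make_gradient_study(
    seed=None,
    conditions: dict[str, float] | None = None,
    n_mice: int = 4,
    images_per_mouse: int = 3,
    image_shape=(96, 96),
    pixel_size: float = 1.0,
    decay_length_um: float = 4.5,
    background: float = 120.0,
    mouse_background_sd: float = 8.0,
    noise_sd: float = 20.0,
    tube_radius_um: float = 4.0,
):
    """Simulate a two-condition gradient experiment at desk scale.

    Conditions share the decay length but differ in amplitude, so their
    true profiles differ at the vessel (0 µm) and coincide once the
    exponential has decayed (beyond ~30 µm at the default 4.5 µm decay
    length). Biological replicate structure is explicit: each mouse gets
    its own staining background (normal around ``background``), shared by
    that mouse's images, so the mouse — not the pixel — carries the
    between-replicate variance.

    Returns ``(images, masks, grouping, truth)`` ready for
    :class:`perilymph.gradient.GradientAnalysis`.
    """
    if conditions is None:
        conditions = {"WT": 800.0, "uPAmut": 200.0}
    gen = _rng(seed)
    ny, nx = image_shape
    tube = TubeSpec(
        control_points=[(0.0, (nx // 2) * pixel_size), ((ny - 1) * pixel_size, (nx // 2) * pixel_size)],
        radius_um=tube_radius_um,
    )
    mask = make_vessel_mask(image_shape, pixel_size, geometry=tube)
    images, masks, rows = [], [], []
    for cond, amplitude in conditions.items():
        for m in range(n_mice):
            mouse_id = f"{cond}_m{m}"
            b_mouse = max(0.0, background + gen.normal(0.0, mouse_background_sd))
            for k in range(images_per_mouse):
                p = GradientFieldParams(
                    amplitude=amplitude,
                    background=b_mouse,
                    decay_length_um=decay_length_um,
                    noise_sd=noise_sd,
                )
                images.append(make_gradient_image(mask, p, rng=gen))
                masks.append(mask)
                rows.append(
                    {"image_id": f"{mouse_id}_i{k}", "mouse_id": mouse_id, "condition": cond}
                )
    grouping = pd.DataFrame(rows)
    truth = {
        "conditions": dict(conditions),
        "decay_length_um": decay_length_um,
        "background": background,
    }
    return images, masks, grouping, truth
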