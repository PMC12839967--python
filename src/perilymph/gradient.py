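"""Perilymphatic gradient quantification.

The central measurement of the package: given a fluorescence image and a
binary lymphatic-vessel mask, quantify how staining intensity decays with
distance from the nearest vessel.

Procedure
---------
1. A Euclidean distance transform of the vessel mask gives every off-vessel
   pixel its shortest physical distance (µm) to a vessel pixel
   (:func:`distance_map`).
2. Distances are rounded to integer µm (half away from zero) and pixel
   intensities sharing an integer distance are averaged, yielding one
   distance-gradient vector per image (:func:`bin_profile`).
3. Per-image vectors are averaged into one profile per biological
   replicate (mouse), then per condition (:func:`average_profiles`); the
   mouse — not the image — is the unit of analysis.
4. Profiles are normalized to the reference condition's intensity at the
   vessel wall, i.e. its 0 µm bin (:func:`normalize_profiles`).
5. Point readouts (intensity at 0 / 30 / 60 µm and the 60:0 ratio) come
   from :func:`profile_summary`; :func:`fit_decay` additionally fits an
   exponential decay ``I(d) = b + A·exp(-d/λ)`` for parameter-recovery
   checks on synthetic data.

:class:`GradientAnalysis` packages steps 1–5 as a model object whose
``fit()`` returns a :class:`GradientResults` with summaries, per-mouse
values and between-condition tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from . import stats
from .types import ImageStack, VesselMask

__all__ = [
    "DistanceMap",
    "IntensityProfile",
    "ProfileSummary",
    "DecayFit",
    "distance_map",
    "bin_profile",
    "average_profiles",
    "normalize_profiles",
    "profile_summary",
    "fit_decay",
    "GradientAnalysis",
    "GradientResults",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# distance transform


@dataclass
class DistanceMap:
    """Per-pixel shortest physical distance (µm) to the nearest vessel pixel.

    ``on_vessel`` flags vessel pixels themselves; their distance is 0.
    """

    distance_um: np.ndarray
    on_vessel: np.ndarray
    spacing: tuple[float, ...]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.distance_um.shape


def distance_map(mask: VesselMask) -> DistanceMap:
    """Exact Euclidean distance transform of a vessel mask.

    Every pixel's distance equals the minimum over all mask pixels of the
    centre-to-centre Euclidean distance, with anisotropic pixel spacing
    honoured (µm). Vessel pixels get distance 0.
    """
    if mask.n_vessel_pixels == 0:
        raise ValueError("vessel mask is empty: cannot compute distances")
    dist = ndimage.distance_transform_edt(~mask.data, sampling=mask.spacing)
    return DistanceMap(distance_um=dist, on_vessel=mask.data.copy(), spacing=mask.spacing)


# ---------------------------------------------------------------------------
# profiles


MISSING = np.nan


@dataclass
class IntensityProfile:
    """Mean intensity per integer-µm distance bin from the nearest vessel.

    Bin index equals integer distance; bins without enough pixels carry
    NaN (missing), never zero. ``n_units`` counts contributing profiles at
    averaged levels (images per mouse, mice per condition).
    """

    distance_um: np.ndarray
    mean_intensity: np.ndarray
    n_pixels: np.ndarray
    n_units: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.distance_um = np.asarray(self.distance_um, dtype=int)
        self.mean_intensity = np.asarray(self.mean_intensity, dtype=float)
        self.n_pixels = np.asarray(self.n_pixels, dtype=int)
        if self.n_units is not None:
            self.n_units = np.asarray(self.n_units, dtype=int)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.mean_intensity)

    def value_at(self, distance: int) -> float:
        """Mean intensity at an integer distance; NaN when missing."""
        idx = np.flatnonzero(self.distance_um == int(distance))
        if len(idx) == 0:
            return float("nan")
        return float(self.mean_intensity[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        d = {
            "distance_um": self.distance_um,
            "mean_intensity": self.mean_intensity,
            "n_pixels": self.n_pixels,
        }
        if self.n_units is not None:
            d["n_units"] = self.n_units
        df = pd.DataFrame(d)
        for k, v in self.provenance.items():
            df[k] = v
        return df


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # np.round would round half to even; the binning convention is half
    # away from zero (distances are non-negative, so floor(x + 0.5)).
    return np.floor(x + 0.5).astype(int)


def bin_profile(
    image: ImageStack,
    dmap: DistanceMap,
    d_max: float = 80.0,
    min_count: int = 10,
    include_vessel_as_zero: bool = False,
    provenance: dict | None = None,
) -> IntensityProfile:
    """Average pixel intensities by integer-µm distance from the vessel.

    Off-vessel pixels are assigned the bin ``round(distance)`` (half away
    from zero) and averaged per bin; on-vessel pixels are excluded — the
    profile describes the *non-masked* tissue. With pixel sizes much above
    0.5 µm bin 0 can therefore be empty; ``include_vessel_as_zero`` places
    the vessel pixels themselves into bin 0 for such coarse images.

    Bins with fewer than ``min_count`` member pixels are marked missing
    (NaN) and excluded from all downstream averaging.
    """
    if image.data.shape != dmap.shape:
        raise ValueError(
            f"image shape {image.data.shape} does not match distance map {dmap.shape}"
        )
    d_max_bin = int(d_max)
    off = ~dmap.on_vessel
    bins = _round_half_away(dmap.distance_um[off])
    vals = np.asarray(image.data, dtype=float)[off]
    keep = bins <= d_max_bin
    bins, vals = bins[keep], vals[keep]

    n_bins = d_max_bin + 1
    counts = np.bincount(bins, minlength=n_bins)
    sums = np.bincount(bins, weights=vals, minlength=n_bins)
    if include_vessel_as_zero:
        counts[0] += int(dmap.on_vessel.sum())
        sums[0] += float(np.asarray(image.data, dtype=float)[dmap.on_vessel].sum())

    mean = np.full(n_bins, MISSING)
    ok = counts >= max(min_count, 1)
    mean[ok] = sums[ok] / counts[ok]
    return IntensityProfile(
        distance_um=np.arange(n_bins),
        mean_intensity=mean,
        n_pixels=counts,
        provenance=dict(provenance or {}),
    )


def average_profiles(
    profiles: Sequence[IntensityProfile],
    level: str = "replicate",
    provenance: dict | None = None,
) -> IntensityProfile:
    """Unweighted per-bin mean over profiles sharing a bin grid.

    Implements the replicate hierarchy: several images from one mouse ear
    average into one biological replicate, and replicates average into a
    condition profile. A bin enters the mean only for inputs where it is
    non-missing; bins missing everywhere stay missing. Per-bin ``n_units``
    records how many inputs contributed.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to average")
    grid = profiles[0].distance_um
    for p in profiles[1:]:
        if not np.array_equal(p.distance_um, grid):
            raise ValueError("profiles do not share a bin grid")
    if len({p.normalized for p in profiles}) > 1:
        raise ValueError("cannot mix normalized and raw profiles")

    values = np.vstack([p.mean_intensity for p in profiles])
    n_units = np.sum(~np.isnan(values), axis=0)
    mean = np.full(len(grid), MISSING)
    has = n_units > 0
    with np.errstate(invalid="ignore"):
        mean[has] = np.nanmean(values[:, has], axis=0)
    n_pixels = np.sum([p.n_pixels for p in profiles], axis=0)
    prov = dict(provenance or {})
    prov.setdefault("level", level)
    return IntensityProfile(
        distance_um=grid.copy(),
        mean_intensity=mean,
        n_pixels=n_pixels,
        n_units=n_units,
        provenance=prov,
        normalized=profiles[0].normalized,
    )


def normalize_profiles(
    profiles: Mapping[str, IntensityProfile], reference: str
) -> dict[str, IntensityProfile]:
    """Normalize condition profiles to the reference condition at 0 µm.

    Every profile's bins are divided by the reference condition's mean
    bin-0 intensity, so the reference profile reads 1.0 at the vessel.
    Normalizing an already-normalized set against the same reference is the
    identity (the reference bin 0 is then exactly 1).
    """
    if reference not in profiles:
        raise ValueError(f"reference condition {reference!r} not among {list(profiles)}")
    ref_val = profiles[reference].value_at(0)
    if np.isnan(ref_val):
        raise ValueError(f"reference condition {reference!r} has no defined 0 µm bin")
    if ref_val <= 0:
        raise ValueError(f"reference 0 µm intensity must be positive, got {ref_val}")
    out = {}
    for cond, p in profiles.items():
        out[cond] = replace(
            p,
            mean_intensity=p.mean_intensity / ref_val,
            distance_um=p.distance_um.copy(),
            n_pixels=p.n_pixels.copy(),
            n_units=None if p.n_units is None else p.n_units.copy(),
            provenance={**p.provenance, "normalized_to": reference},
            normalized=True,
        )
    return out


# ---------------------------------------------------------------------------
# summaries and decay fit


@dataclass
class ProfileSummary:
    """Point readouts of a finalized profile.

    ``ratio_60_0`` is the 60 µm : 0 µm intensity ratio — a far-field
    gradient-reach index; it is undefined (NaN) when either bin is missing
    or the 0 µm value is not positive. ``background`` carries the isotype
    staining floor for plotting/reporting; it is only subtracted when the
    summary was built with ``subtract_background=True``.
    """

    i0: float
    i30: float
    i60: float
    ratio_60_0: float
    background: float
    background_subtracted: bool = False


def profile_summary(
    profile: IntensityProfile,
    background: float = 0.0,
    subtract_background: bool = False,
) -> ProfileSummary:
    i0, i30, i60 = (profile.value_at(d) for d in (0, 30, 60))
    b = background if subtract_background else 0.0
    num, den = i60 - b, i0 - b
    ratio = num / den if np.isfinite(num) and np.isfinite(den) and den > 0 else float("nan")
    return ProfileSummary(
        i0=i0,
        i30=i30,
        i60=i60,
        ratio_60_0=ratio,
        background=background,
        background_subtracted=subtract_background,
    )


@dataclass
class DecayFit:
    """Exponential-decay fit ``I(d) = b + A·exp(-d/λ)`` of a profile."""

    amplitude: float
    decay_length_um: float
    background: float
    rmse: float
    n_bins: int


def fit_decay(
    profile: IntensityProfile, background: float, min_bins: int = 4
) -> DecayFit:
    """Weighted least-squares exponential fit with a fixed background.

    Bins are weighted by pixel count; at least ``min_bins`` non-missing
    bins above the background level are required — a profile flat at
    background has no decaying component to fit.
    """
    ok = profile.defined & (profile.n_pixels > 0)
    d = profile.distance_um[ok].astype(float)
    y = profile.mean_intensity[ok]
    n = profile.n_pixels[ok].astype(float)
    above = y > background
    if int(above.sum()) < min_bins:
        raise ValueError(
            f"need at least {min_bins} bins above background to fit a decay; "
            f"got {int(above.sum())}"
        )
    a0 = float(np.max(y) - background)
    # log-linear slope for the initial decay-length guess
    dd, yy = d[above], y[above] - background
    slope = np.polyfit(dd, np.log(yy), 1)[0] if len(dd) >= 2 else -0.1
    lam0 = -1.0 / slope if slope < 0 else 10.0

    def model(x, a, lam):
        return background + a * np.exp(-x / lam)

    try:
        popt, _ = optimize.curve_fit(
            model,
            d,
            y,
            p0=(max(a0, 1e-9), max(lam0, 1e-3)),
            sigma=1.0 / np.sqrt(n),
            bounds=([0.0, 1e-6], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as err:  # pragma: no cover - pathological inputs
        raise ValueError(f"decay fit did not converge: {err}") from err
    resid = y - model(d, *popt)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return DecayFit(
        amplitude=float(popt[0]),
        decay_length_um=float(popt[1]),
        background=background,
        rmse=rmse,
        n_bins=int(len(d)),
    )


# ---------------------------------------------------------------------------
# model object


class GradientAnalysis:
    """Gradient quantification for a set of images grouped by mouse/condition.

    Parameters
    ----------
    images
        2-D :class:`ImageStack` objects (project 3-D stacks first with
        :func:`perilymph.io.max_project`).
    masks
        One :class:`VesselMask` per image, or a single shared mask.
    grouping
        DataFrame with one row per image, columns ``image_id``,
        ``mouse_id``, ``condition``, aligned with ``images`` by position.
    reference
        Condition whose 0 µm intensity anchors the normalization; defaults
        to the first-listed condition.
    background
        Isotype staining level (a.u.), reported alongside summaries.
    """

    def __init__(
        self,
        images: Sequence[ImageStack],
        masks: VesselMask | Sequence[VesselMask],
        grouping: pd.DataFrame,
        *,
        d_max: float = 80.0,
        min_count: int = 10,
        include_vessel_as_zero: bool = False,
        reference: str | None = None,
        background: float = 0.0,
    ) -> None:
        images = list(images)
        if isinstance(masks, VesselMask):
            masks = [masks] * len(images)
        masks = list(masks)
        if len(masks) != len(images):
            raise ValueError("need one mask per image (or a single shared mask)")
        grouping = pd.DataFrame(grouping).reset_index(drop=True)
        for col in ("image_id", "mouse_id", "condition"):
            if col not in grouping.columns:
                raise ValueError(f"grouping table missing column {col!r}")
        if len(grouping) != len(images):
            raise ValueError("grouping must have one row per image")
        for img, msk in zip(images, masks):
            msk.check_aligned(img)
        self.images = images
        self.masks = masks
        self.grouping = grouping
        self.d_max = d_max
        self.min_count = min_count
        self.include_vessel_as_zero = include_vessel_as_zero
        self.conditions = list(dict.fromkeys(grouping["condition"]))
        self.reference = reference if reference is not None else self.conditions[0]
        if self.reference not in self.conditions:
            raise ValueError(f"reference {self.reference!r} not among conditions")
        self.background = background

    def fit(self) -> "GradientResults":
        # distance maps are cached per mask object so a shared mask is
        # transformed once
        dmaps: dict[int, DistanceMap] = {}
        image_profiles: list[IntensityProfile] = []
        for img, msk, (_, row) in zip(self.images, self.masks, self.grouping.iterrows()):
            key = id(msk)
            if key not in dmaps:
                dmaps[key] = distance_map(msk)
            image_profiles.append(
                bin_profile(
                    img,
                    dmaps[key],
                    d_max=self.d_max,
                    min_count=self.min_count,
                    include_vessel_as_zero=self.include_vessel_as_zero,
                    provenance={
                        "image_id": row["image_id"],
                        "mouse_id": row["mouse_id"],
                        "condition": row["condition"],
                        "level": "image",
                    },
                )
            )

        mouse_profiles: dict[tuple[str, str], IntensityProfile] = {}
        for (cond, mouse), idx in self.grouping.groupby(
            ["condition", "mouse_id"], sort=False
        ).groups.items():
            mouse_profiles[(cond, mouse)] = average_profiles(
                [image_profiles[i] for i in idx],
                level="mouse",
                provenance={"mouse_id": mouse, "condition": cond},
            )

        condition_profiles: dict[str, IntensityProfile] = {}
        for cond in self.conditions:
            members = [p for (c, _), p in mouse_profiles.items() if c == cond]
            condition_profiles[cond] = average_profiles(
                members, level="condition", provenance={"condition": cond}
            )

        normalized = normalize_profiles(condition_profiles, self.reference)
        ref_val = condition_profiles[self.reference].value_at(0)
        return GradientResults(
            model=self,
            image_profiles=image_profiles,
            mouse_profiles=mouse_profiles,
            condition_profiles=condition_profiles,
            normalized_profiles=normalized,
            reference_value=ref_val,
        )


class GradientResults:
    """Fitted gradient profiles at image, mouse and condition level."""

    def __init__(
        self,
        model: GradientAnalysis,
        image_profiles,
        mouse_profiles,
        condition_profiles,
        normalized_profiles,
        reference_value: float,
    ) -> None:
        self.model = model
        self.image_profiles = image_profiles
        self.mouse_profiles = mouse_profiles
        self.condition_profiles = condition_profiles
        self.normalized_profiles = normalized_profiles
        self.reference_value = reference_value

    def summary(self, normalized: bool = False, subtract_background: bool = False) -> pd.DataFrame:
        """Per-condition point readouts (I0, I30, I60, 60:0 ratio)."""
        src = self.normalized_profiles if normalized else self.condition_profiles
        bg = self.model.background
        if normalized and self.reference_value:
            bg = bg / self.reference_value
        rows = []
        for cond in self.model.conditions:
            p = src[cond]
            s = profile_summary(p, background=bg, subtract_background=subtract_background)
            n_mice = int(np.nanmax(p.n_units)) if p.n_units is not None else 1
            rows.append(
                {
                    "condition": cond,
                    "I0": s.i0,
                    "I30": s.i30,
                    "I60": s.i60,
                    "ratio_60_0": s.ratio_60_0,
                    "background": s.background,
                    "n_mice": n_mice,
                }
            )
        return pd.DataFrame(rows)

    def values_at(self, distance: int, normalized: bool = False) -> pd.DataFrame:
        """Per-mouse profile values at one distance (tidy, for statistics)."""
        scale = self.reference_value if normalized else 1.0
        rows = [
            {
                "condition": cond,
                "mouse_id": mouse,
                "value": p.value_at(distance) / scale,
            }
            for (cond, mouse), p in self.mouse_profiles.items()
        ]
        return pd.DataFrame(rows)

    def test_at_distance(
        self, distance: int, cond_a: str, cond_b: str, paired: bool = False
    ) -> "stats.ComparisonResult":
        """Two-condition Student t test on per-mouse values at one distance."""
        df = self.values_at(distance).dropna(subset=["value"])
        xa = df.loc[df["condition"] == cond_a, "value"].to_numpy()
        xb = df.loc[df["condition"] == cond_b, "value"].to_numpy()
        return stats.compare_two(
            xa, xb, paired=paired, grouping=f"{cond_a} vs {cond_b} @ {distance} µm"
        )

    def fit_decay(self, condition: str, background: float | None = None) -> DecayFit:
        bg = self.model.background if background is None else background
        return fit_decay(self.condition_profiles[condition], background=bg)

    def profiles_frame(self, level: str = "condition") -> pd.DataFrame:
        """Tidy long-format profiles for export (``level``: image/mouse/condition)."""
        if level == "image":
            frames = [p.to_frame() for p in self.image_profiles]
        elif level == "mouse":
            frames = [p.to_frame() for p in self.mouse_profiles.values()]
        elif level == "condition":
            frames = [p.to_frame() for p in self.condition_profiles.values()]
        else:
            raise ValueError(f"unknown level {level!r}")
        return pd.concat(frames, ignore_index=True)

    def plot(self, ax=None, normalized: bool = True, show_background: bool = True):
        """Condition profiles vs distance, with the isotype floor as a line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        src = self.normalized_profiles if normalized else self.condition_profiles
        for cond in self.model.conditions:
            p = src[cond]
            ax.plot(p.distance_um[p.defined], p.mean_intensity[p.defined], label=cond)
        if show_background and self.model.background:
            bg = self.model.background
            if normalized and self.reference_value:
                bg = bg / self.reference_value
            ax.axhline(bg, ls="--", c="gray", label="isotype background")
        ax.set_xlabel("distance from lymphatic vessel (µm)")
        ax.set_ylabel("normalized intensity" if normalized else "intensity (a.u.)")
        ax.legend()
        return ax
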