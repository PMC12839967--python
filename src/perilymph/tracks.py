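"""Cell-track motility metrics and assay inclusion filters.

Metric definitions (per track, positions p₀…p_N in µm):

* path length      L  = Σ‖pᵢ₊₁ − pᵢ‖  (total track length)
* displacement     D  = ‖p_N − p₀‖    (Euclidean distance, origin→endpoint)
* y-displacement   Dy = (p_N − p₀)·ŷ  (signed, along the stimulus axis)
* speed            L / duration       (µm/min)
* directionality   L / D              (≥ 1; undefined when D = 0)
* chemotactic index D / L             (track straightness, ∈ [0, 1])
* yFMI             Dy / L             (forward-migration index, ∈ [−1, 1])

Note directionality as defined here is the *reciprocal* of the
chemotactic index; both are computed exactly as defined and reported side
by side to avoid convention confusion. Undefined metrics are NaN, never
zero, and are excluded from cohort means.

Inclusion filters (strict inequalities):

* 3-D chemotaxis assay: accumulated path length L > 50 µm.
* crawling assay: recording duration > 10 min and L > 60 µm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats
from .types import Track

__all__ = [
    "TrackMetrics",
    "compute_metrics",
    "filter_chemotaxis_tracks",
    "filter_crawling_tracks",
    "cohort_summary",
    "TrackAnalysis",
    "TrackResults",
]

logger = logging.getLogger(__name__)

ASSAYS = ("chemotaxis3d", "crawling")
_Y = 1  # stimulus axis column in (x, y[, z])


@dataclass
class TrackMetrics:
    track_id: str
    condition: str
    assay: str
    n_points: int
    duration_s: float
    path_length_um: float
    displacement_um: float
    y_displacement_um: float
    euclidean_distance_um: float
    speed_um_min: float
    directionality: float
    chemotactic_index: float
    yfmi: float


def compute_metrics(track: Track, condition: str | None = None) -> TrackMetrics:
    """Compute all motility metrics for one track."""
    steps = np.diff(track.positions, axis=0)
    L = float(np.linalg.norm(steps, axis=1).sum())
    end_to_end = track.positions[-1] - track.positions[0]
    D = float(np.linalg.norm(end_to_end))
    Dy = float(end_to_end[_Y])
    duration = track.duration_s
    return TrackMetrics(
        track_id=track.track_id,
        condition=condition if condition is not None else track.condition,
        assay=track.assay,
        n_points=track.n_points,
        duration_s=duration,
        path_length_um=L,
        displacement_um=D,
        y_displacement_um=Dy,
        euclidean_distance_um=D,
        speed_um_min=L / (duration / 60.0),
        directionality=L / D if D > 0 else float("nan"),
        chemotactic_index=D / L if L > 0 else float("nan"),
        yfmi=Dy / L if L > 0 else float("nan"),
    )


def _path_length(track: Track) -> float:
    return float(np.linalg.norm(np.diff(track.positions, axis=0), axis=1).sum())


def filter_chemotaxis_tracks(tracks: Iterable[Track]) -> list[Track]:
    """Keep motile cells: accumulated path length strictly above 50 µm."""
    kept = [tr for tr in tracks if _path_length(tr) > 50.0]
    if not kept:
        logger.warning("filter_chemotaxis_tracks: no track passed the >50 µm filter")
    return kept


def filter_crawling_tracks(tracks: Iterable[Track]) -> list[Track]:
    """Keep tracks recorded for >10 min with total path length >60 µm."""
    kept = [tr for tr in tracks if tr.duration_s > 600.0 and _path_length(tr) > 60.0]
    if not kept:
        logger.warning("filter_crawling_tracks: no track passed the inclusion filters")
    return kept


_FILTERS = {"chemotaxis3d": filter_chemotaxis_tracks, "crawling": filter_crawling_tracks}

_METRIC_COLS = [
    "duration_s",
    "path_length_um",
    "displacement_um",
    "y_displacement_um",
    "euclidean_distance_um",
    "speed_um_min",
    "directionality",
    "chemotactic_index",
    "yfmi",
]


def cohort_summary(
    tracks: Sequence[Track],
    assay: str,
    conditions: Mapping[str, str] | None = None,
    apply_filter: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter, measure and aggregate a cohort of tracks.

    ``conditions`` maps track_id -> condition label (falls back to the
    tracks' own ``condition`` attribute). Returns (per-track tidy table,
    per-condition mean ± SEM table). NaN metrics are excluded per metric,
    with the contributing ``n`` reported.
    """
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r}; expected one of {ASSAYS}")
    tags = {tr.assay for tr in tracks if tr.assay}
    if len(tags) > 1:
        raise ValueError(f"mixed assay tags in one cohort: {sorted(tags)}")
    if tags and tags != {assay}:
        raise ValueError(f"tracks tagged {tags.pop()!r} analyzed as {assay!r}")

    selected = _FILTERS[assay](tracks) if apply_filter else list(tracks)
    rows = []
    for tr in selected:
        cond = conditions.get(tr.track_id, tr.condition) if conditions else tr.condition
        m = compute_metrics(tr, condition=cond)
        rows.append({f.name: getattr(m, f.name) for f in fields(TrackMetrics)})
    per_track = pd.DataFrame(
        rows, columns=[f.name for f in fields(TrackMetrics)]
    )

    summaries = []
    if len(per_track):
        for cond, g in per_track.groupby("condition", sort=False):
            entry = {"condition": cond, "n_tracks": len(g)}
            for col in _METRIC_COLS:
                v = g[col].dropna()
                entry[f"{col}_mean"] = v.mean() if len(v) else float("nan")
                entry[f"{col}_sem"] = (
                    v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else (0.0 if len(v) == 1 else float("nan"))
                )
                entry[f"{col}_n"] = len(v)
            summaries.append(entry)
    summary = pd.DataFrame(summaries)
    return per_track, summary


class TrackAnalysis:
    """Model object for one assay's track cohort.

    Applies the assay's inclusion filter, computes per-track metrics and
    condition-level aggregates; ``fit()`` returns :class:`TrackResults`.
    """

    def __init__(
        self,
        tracks: Sequence[Track],
        assay: str,
        conditions: Mapping[str, str] | None = None,
        apply_filter: bool = True,
    ) -> None:
        if assay not in ASSAYS:
            raise ValueError(f"unknown assay {assay!r}; expected one of {ASSAYS}")
        self.tracks = list(tracks)
        self.assay = assay
        self.conditions = conditions
        self.apply_filter = apply_filter

    def fit(self) -> "TrackResults":
        per_track, summary = cohort_summary(
            self.tracks, self.assay, conditions=self.conditions, apply_filter=self.apply_filter
        )
        return TrackResults(self, per_track, summary)


class TrackResults:
    def __init__(self, model: TrackAnalysis, per_track: pd.DataFrame, summary_df: pd.DataFrame):
        self.model = model
        self.per_track = per_track
        self._summary = summary_df
        self.n_input = len(model.tracks)
        self.n_included = len(per_track)

    def summary(self) -> pd.DataFrame:
        return self._summary

    def compare(self, metric: str, cond_a: str, cond_b: str, paired: bool = False):
        """Unpaired (default) Student t between two conditions on one metric."""
        g = self.per_track
        xa = g.loc[g["condition"] == cond_a, metric].dropna().to_numpy()
        xb = g.loc[g["condition"] == cond_b, metric].dropna().to_numpy()
        return stats.compare_two(xa, xb, paired=paired, grouping=f"{metric}: {cond_a} vs {cond_b}")

    def plot_trajectories(self, ax=None, origin_at_zero: bool = True):
        """All included tracks overlaid from a common origin (rose-style)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        kept_ids = set(self.per_track["track_id"])
        for tr in self.model.tracks:
            if tr.track_id not in kept_ids:
                continue
            p = tr.positions[:, :2]
            if origin_at_zero:
                p = p - p[0]
            ax.plot(p[:, 0], p[:, 1], lw=0.8, alpha=0.7)
        ax.set_xlabel("x (µm)")
        ax.set_ylabel("y (µm)  → stimulus")
        ax.set_aspect("equal")
        return ax
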