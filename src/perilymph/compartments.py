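"""Lymph-node compartment occupancy from exported single-cell tables.

The workflow mirrors a flow-style analysis of segmented tissue sections:

1. Fluorescence gates are derived from cells measured in marker-negative
   tissue areas — the threshold is a high empirical quantile (default
   0.995) of the negative intensity distribution (:func:`derive_gate`).
2. Cells are gated sequentially: valid cell (DAPI⁺ with plausible nuclear
   area) → CD11c⁺ → FITC⁺CD11c⁺ (:func:`apply_gates`).
3. Double-positive (hapten-carrying dendritic) cells are counted per
   compartment; the readouts are the SCS / parenchyma percentages and the
   SCS:parenchyma ratio (:func:`compartment_stats`).
4. Independently, staining intensity can be normalized to compartment
   area (:func:`compartment_intensity`).

Tissue segmentation and nucleus detection are upstream of this module; it
consumes their exported tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GateEntry",
    "GateSpec",
    "derive_gate",
    "derive_gates",
    "apply_gates",
    "CompartmentResult",
    "compartment_stats",
    "compartment_intensity",
    "CompartmentAnalysis",
    "CompartmentResults",
]

MARKERS = ("DAPI", "CD11c", "FITC")


@dataclass
class GateEntry:
    """Threshold for one marker, with its derivation recorded."""

    threshold: float
    quantile: float
    n_negative: int


@dataclass
class GateSpec:
    entries: dict[str, GateEntry] = field(default_factory=dict)

    def threshold(self, marker: str) -> float:
        return self.entries[marker].threshold

    def to_dict(self) -> dict:
        return {
            m: {"threshold": e.threshold, "quantile": e.quantile, "n_negative": e.n_negative}
            for m, e in self.entries.items()
        }


def derive_gate(
    negatives, quantile: float = 0.995, min_negatives: int = 50
) -> GateEntry:
    """Gate threshold = empirical quantile of a marker-negative population.

    Uses linear interpolation between order statistics. The quantile must
    sit in (0.5, 1): a gate below the negative median would be
    meaningless. A floor on the number of negative cells (default 50)
    guards against gates derived from too few reference cells.
    """
    neg = np.asarray(negatives, dtype=float)
    if not 0.5 < quantile < 1:
        raise ValueError(f"quantile must be in (0.5, 1), got {quantile}")
    if len(neg) < min_negatives:
        raise ValueError(
            f"only {len(neg)} negative-reference cells; need >= {min_negatives}"
        )
    thr = float(np.quantile(neg, quantile))  # linear interpolation (default)
    return GateEntry(threshold=thr, quantile=quantile, n_negative=len(neg))


def derive_gates(
    negatives: Mapping[str, np.ndarray], quantile: float = 0.995, min_negatives: int = 50
) -> GateSpec:
    """Derive one gate per marker from its negative reference set."""
    return GateSpec(
        entries={
            m: derive_gate(v, quantile=quantile, min_negatives=min_negatives)
            for m, v in negatives.items()
        }
    )


def apply_gates(
    cells: pd.DataFrame,
    gates: GateSpec,
    area_range: tuple[float, float] = (10.0, 200.0),
) -> pd.DataFrame:
    """Sequential gating; annotates each cell with its deepest gate.

    Requires intensity columns ``int_DAPI``, ``int_CD11c``, ``int_FITC``
    and ``area_um2``. The valid-cell gate is DAPI above threshold AND
    nuclear area within ``area_range`` (µm²); CD11c⁺ is evaluated within
    valid cells, FITC⁺ within CD11c⁺ cells. Gate flags use strict ``>``.
    """
    for m in MARKERS:
        if m not in gates.entries:
            raise ValueError(f"gate for marker {m!r} missing")
        col = f"int_{m}"
        if col not in cells.columns:
            raise ValueError(f"marker column {col!r} missing from cell table")
    if "area_um2" not in cells.columns:
        raise ValueError("cell table missing 'area_um2' column")
    lo, hi = area_range
    out = cells.copy()
    out["gate_valid"] = (
        (out["int_DAPI"] > gates.threshold("DAPI"))
        & (out["area_um2"] >= lo)
        & (out["area_um2"] <= hi)
    )
    out["gate_cd11c"] = out["gate_valid"] & (out["int_CD11c"] > gates.threshold("CD11c"))
    out["gate_fitc_cd11c"] = out["gate_cd11c"] & (out["int_FITC"] > gates.threshold("FITC"))
    deepest = np.where(
        out["gate_fitc_cd11c"],
        "fitc_cd11c",
        np.where(out["gate_cd11c"], "cd11c", np.where(out["gate_valid"], "valid", "none")),
    )
    out["deepest_gate"] = deepest
    return out


@dataclass
class CompartmentResult:
    """Compartment occupancy of gated double-positive cells.

    Percentages are over SCS + parenchyma only; other compartments are
    carried in ``counts`` but excluded from the ratio. ``ratio`` is NaN
    (undefined) when no double-positive sits in the parenchyma.
    """

    counts: dict[str, int]
    pct_scs: float
    pct_parenchyma: float
    ratio_scs_parenchyma: float

    @property
    def n_double_positive(self) -> int:
        return sum(self.counts.values())


def compartment_stats(gated: pd.DataFrame) -> CompartmentResult:
    """Count FITC⁺CD11c⁺ cells per compartment and form the SCS readouts."""
    if "gate_fitc_cd11c" not in gated.columns:
        raise ValueError("run apply_gates first: 'gate_fitc_cd11c' column missing")
    dp = gated[gated["gate_fitc_cd11c"]]
    if len(dp) == 0:
        raise ValueError("no double-positive (FITC+CD11c+) cell to summarize")
    counts = dp["compartment"].value_counts().to_dict()
    n_scs = int(counts.get("SCS", 0))
    n_par = int(counts.get("parenchyma", 0))
    denom = n_scs + n_par
    if denom == 0:
        raise ValueError("no double-positive cell in SCS or parenchyma")
    ratio = n_scs / n_par if n_par > 0 else float("nan")
    return CompartmentResult(
        counts={k: int(v) for k, v in counts.items()},
        pct_scs=100.0 * n_scs / denom,
        pct_parenchyma=100.0 * n_par / denom,
        ratio_scs_parenchyma=ratio,
    )


def compartment_intensity(
    table: pd.DataFrame,
    areas: Mapping[str, float],
    intensity_col: str = "intensity",
    compartment_col: str = "compartment",
) -> pd.Series:
    """Per-compartment staining intensity normalized to compartment area.

    ``table`` holds per-cell or per-pixel intensities with compartment
    labels; ``areas`` gives each compartment's area in µm². Returns summed
    intensity / area (a.u./µm²) per requested compartment.
    """
    out = {}
    for comp, area in areas.items():
        if area <= 0:
            raise ValueError(f"compartment {comp!r} has non-positive area {area}")
        total = float(table.loc[table[compartment_col] == comp, intensity_col].sum())
        out[comp] = total / float(area)
    return pd.Series(out, name="intensity_per_area")


class CompartmentAnalysis:
    """Model object: cell table + negative references -> occupancy readouts."""

    def __init__(
        self,
        cells: pd.DataFrame,
        negatives: Mapping[str, np.ndarray],
        quantile: float = 0.995,
        area_range: tuple[float, float] = (10.0, 200.0),
        min_negatives: int = 50,
    ) -> None:
        self.cells = cells
        self.negatives = negatives
        self.quantile = quantile
        self.area_range = area_range
        self.min_negatives = min_negatives

    def fit(self) -> "CompartmentResults":
        gates = derive_gates(
            self.negatives, quantile=self.quantile, min_negatives=self.min_negatives
        )
        gated = apply_gates(self.cells, gates, area_range=self.area_range)
        result = compartment_stats(gated)
        return CompartmentResults(gates, gated, result)


class CompartmentResults:
    def __init__(self, gates: GateSpec, gated: pd.DataFrame, result: CompartmentResult):
        self.gates = gates
        self.gated = gated
        self.result = result

    def summary(self) -> pd.DataFrame:
        r = self.result
        return pd.DataFrame(
            [
                {
                    "n_double_positive": r.n_double_positive,
                    "n_scs": r.counts.get("SCS", 0),
                    "n_parenchyma": r.counts.get("parenchyma", 0),
                    "pct_scs": r.pct_scs,
                    "pct_parenchyma": r.pct_parenchyma,
                    "ratio_scs_parenchyma": r.ratio_scs_parenchyma,
                }
            ]
        )
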