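"""Positivity thresholding, marker-panel cell typing, and saturation QC.

A cell is "positive" for a gene when its dot count strictly exceeds 10% of
that gene's per-cell maximum, capped at 3 dots for abundant genes (maxima
over 31).  Cell types are called combinatorially: at least two of a type's
selective markers positive, at most one positive marker from any other
type, with per-type single-marker exceptions (e.g. club: >3 Scgb1a1 dots).
Saturation flags mark counts approaching the geometric capacity of the
cell footprint (cell area / mean dot area ≈ 80 for typical cells).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .spots import CountsMatrix

NA_LABEL = "NA"


@dataclass
class ThresholdRule:
    """Per-gene positivity rule: threshold = min(fraction·max, cap), strict >.

    With the defaults the cap binds exactly for per-cell maxima over 31
    (0.10 × 31 = 3.1 > 3); below that the 10% rule applies unrounded.
    """

    fraction: float = 0.10
    cap: float = 3.0
    cap_trigger_max: int = 31

    def __post_init__(self):
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        if self.cap <= 0:
            raise ValueError("cap must be positive")
        if self.fraction * self.cap_trigger_max < self.cap:
            raise ValueError(
                "inconsistent rule: fraction*cap_trigger_max must be >= cap"
            )


def positivity_threshold(max_dots_for_gene: float, rule: ThresholdRule | None = None) -> float:
    """Threshold for one gene given its observed per-cell maximum."""
    rule = rule or ThresholdRule()
    if max_dots_for_gene < 0:
        raise ValueError("max dot count cannot be negative")
    return min(rule.fraction * max_dots_for_gene, rule.cap)


def call_positivity(
    counts: CountsMatrix | pd.DataFrame, rule: ThresholdRule | None = None
) -> pd.DataFrame:
    """Boolean cells × genes positivity using each gene's own maximum."""
    rule = rule or ThresholdRule()
    df = counts.counts if isinstance(counts, CountsMatrix) else counts
    if (df.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    thresholds = df.max(axis=0).astype(float).apply(positivity_threshold, rule=rule)
    return df.gt(thresholds, axis=1)


@dataclass
class MarkerSet:
    markers: list[str]
    min_positive: int = 2
    fixed_cutoff: float | None = None  # single-marker exception: counts > cutoff

    def __post_init__(self):
        if not self.markers:
            raise ValueError("a marker set needs at least one gene")
        if self.fixed_cutoff is not None and self.fixed_cutoff <= 0:
            raise ValueError("fixed_cutoff must be positive")


@dataclass
class MarkerPanel:
    """Cell types with their selective markers and calling parameters."""

    types: dict[str, MarkerSet]
    max_foreign: int = 1

    @classmethod
    def from_yaml(cls, path: str) -> "MarkerPanel":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        types = {}
        for name, spec in raw["types"].items():
            types[name] = MarkerSet(
                markers=list(spec["markers"]),
                min_positive=int(spec.get("min_positive", 2)),
                fixed_cutoff=spec.get("fixed_cutoff"),
            )
        return cls(types, max_foreign=int(raw.get("max_foreign", 1)))

    def validate_against(self, genes) -> None:
        genes = set(genes)
        for name, ms in self.types.items():
            missing = [m for m in ms.markers if m not in genes]
            if missing:
                raise ValueError(
                    f"markers {missing} of type {name!r} missing from counts matrix"
                )


def annotate_by_panel(
    positivity: pd.DataFrame,
    counts: CountsMatrix | pd.DataFrame,
    panel: MarkerPanel,
) -> pd.DataFrame:
    """Combinatorial cell typing.

    A type is satisfied for a cell when (its own positive markers reach
    ``min_positive``, or its fixed-cutoff exception holds) and no other
    type contributes more than ``max_foreign`` positive markers.  Exactly
    one satisfied type labels the cell; zero or several yield "NA", with
    the competing types recorded.
    """
    cdf = counts.counts if isinstance(counts, CountsMatrix) else counts
    panel.validate_against(cdf.columns)
    sat = pd.DataFrame(index=positivity.index)
    own_pos = {
        name: positivity[ms.markers].sum(axis=1) for name, ms in panel.types.items()
    }
    for name, ms in panel.types.items():
        if ms.fixed_cutoff is not None:
            core = cdf[ms.markers].gt(ms.fixed_cutoff).sum(axis=1) >= ms.min_positive
        else:
            core = own_pos[name] >= ms.min_positive
        foreign_ok = pd.Series(True, index=positivity.index)
        for other in panel.types:
            if other != name:
                foreign_ok &= own_pos[other] <= panel.max_foreign
        sat[name] = core & foreign_ok
    n_sat = sat.sum(axis=1)
    labels = pd.Series(NA_LABEL, index=positivity.index, name="label")
    single = n_sat == 1
    labels[single] = sat.loc[single].idxmax(axis=1)
    competing = sat.apply(lambda r: ";".join(sat.columns[r.to_numpy()]), axis=1)
    out = pd.DataFrame({"label": labels, "n_satisfied": n_sat,
                        "satisfied_types": competing})
    out.index.name = "cell_id"
    return out


ALVEOLAR_GENES = ("Ascl1", "Scgb1a1", "Cyp2f2", "Sftpc", "Lyz2", "Cd74", "Ager")


def annotate_alveolar(
    counts: CountsMatrix | pd.DataFrame, cutoff: float = 3.0
) -> pd.Series:
    """Fixed-order boolean annotation of the alveolar/airway compartment.

    A gene is "pos" when dots > cutoff (3 by default).  Rules, first match
    wins: NE (Ascl1 pos); secretory (Scgb1a1 pos, Cyp2f2 pos, Ascl1 neg);
    AT2 (Sftpc pos); macrophage (Lyz2 pos, Cd74 pos, Sftpc neg); Lyz2-only
    and Cd74-only immune cells; AT1 (Ager pos, Sftpc neg, Scgb1a1 neg);
    otherwise NA.
    """
    df = counts.counts if isinstance(counts, CountsMatrix) else counts
    missing = [g for g in ALVEOLAR_GENES if g not in df.columns]
    if missing:
        raise ValueError(f"alveolar annotation needs genes {missing}")
    p = df[list(ALVEOLAR_GENES)].gt(cutoff)
    rules = [
        ("NE", p.Ascl1),
        ("secretory", p.Scgb1a1 & p.Cyp2f2 & ~p.Ascl1),
        ("AT2", p.Sftpc),
        ("macrophage", p.Lyz2 & p.Cd74 & ~p.Sftpc),
        ("Lyz2_immune", p.Lyz2 & ~p.Cd74 & ~p.Sftpc),
        ("Cd74_immune", p.Cd74 & ~p.Lyz2 & ~p.Sftpc),
        ("AT1", p.Ager & ~p.Sftpc & ~p.Scgb1a1),
    ]
    labels = pd.Series(NA_LABEL, index=df.index, name="label")
    unset = pd.Series(True, index=df.index)
    for name, cond in rules:
        hit = unset & cond
        labels[hit] = name
        unset &= ~cond
    return labels


def saturation_capacity(cell_area_um2: float, mean_dot_area_um2: float) -> int:
    """How many non-overlapping dots fit a cell footprint: ⌊area / dot area⌋."""
    if cell_area_um2 <= 0 or mean_dot_area_um2 <= 0:
        raise ValueError("areas must be positive")
    return int(math.floor(cell_area_um2 / mean_dot_area_um2))


@dataclass
class SaturationModel:
    """Geometric saturation bound: capacity = ⌊cell area / mean dot area⌋."""

    mean_dot_area_um2: float = 0.55
    flag_fraction: float = 0.7

    def __post_init__(self):
        if self.mean_dot_area_um2 <= 0:
            raise ValueError("mean_dot_area_um2 must be positive")
        if not 0 < self.flag_fraction <= 1:
            raise ValueError("flag_fraction must be in (0, 1]")

    def capacities(self, cell_areas_um2: pd.Series) -> pd.Series:
        return cell_areas_um2.apply(
            lambda a: saturation_capacity(a, self.mean_dot_area_um2)
        ).astype(int)

    def flag(self, counts: pd.DataFrame, cell_areas_um2: pd.Series) -> pd.DataFrame:
        return flag_saturated(counts, self.capacities(cell_areas_um2),
                              self.flag_fraction)


def flag_saturated(
    counts: pd.DataFrame, capacities: pd.Series, fraction: float
) -> pd.DataFrame:
    """Boolean per (cell, gene): count ≥ fraction × that cell's capacity.

    Counts of zero are never flagged (capacity is at least 0 and the flag
    requires a non-zero count to be meaningful only when fraction·capacity
    is 0 too, so the count==0 case is excluded explicitly).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    caps = capacities.reindex(counts.index)
    limit = np.outer(caps.to_numpy(dtype=float) * fraction,
                     np.ones(counts.shape[1]))
    flags = (counts.to_numpy() >= limit) & (counts.to_numpy() > 0)
    return pd.DataFrame(flags, index=counts.index, columns=counts.columns)
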