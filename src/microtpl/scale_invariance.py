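"""Scale-invariance of the heterogeneity slope b across host body sizes,
and dominant-phylum subset fits.

If the spatial aggregation of skin microbes were controlled by the size of
the habitat the host offers, the per-species Taylor slope b would trend with
the species' mean skin area.  ``b_vs_area`` quantifies that trend by OLS of
b on area (A2 or A3), for Type-I and Type-III slopes separately; a flat,
non-significant trend supports scale invariance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import Study
from .tple import (
    GroupedFits,
    InsufficientDataError,
    PleFit,
    fit_ple,
    type1_mean_variance,
    type3_mean_variance,
)

AreaKind = Literal["A2", "A3"]


@dataclass(frozen=True)
class TrendResult:
    """OLS trend of the heterogeneity slope b against species mean skin area."""

    slope: float  # change of b per mm^2 (or per ln mm^2 with log_area)
    p_value: float
    r_squared: float
    n_species: int
    level: str
    area_kind: AreaKind
    log_area: bool = False


def b_vs_area(
    fits: Iterable[PleFit],
    areas: Mapping[str, float],
    area_kind: AreaKind = "A3",
    log_area: bool = False,
) -> TrendResult:
    """Regress per-species fitted b on species mean skin area.

    ``fits`` are per-species fits of one level; ``areas`` maps host species
    to its mean area (mm^2) of the chosen kind.  Species without both a fit
    and an area are excluded; fewer than 3 remaining species is an error.
    """
    fits = list(fits)
    levels = {f.level for f in fits}
    if len(levels) > 1:
        raise ValueError(f"fits mix levels: {sorted(levels)}")
    points = [(areas[f.group_label], f.b) for f in fits if f.group_label in areas]
    if len(points) < 3:
        raise InsufficientDataError(
            f"need >= 3 species with both a fit and an area, got {len(points)}"
        )
    x = np.array([p[0] for p in points], dtype=float)
    if (x <= 0).any():
        raise ValueError("species mean areas must be positive")
    if log_area:
        x = np.log(x)
    y = np.array([p[1] for p in points], dtype=float)
    if np.ptp(y) == 0:
        # constant response: zero trend, no explained variance
        return TrendResult(0.0, 1.0, 0.0, len(points), levels.pop(), area_kind, log_area)
    res = stats.linregress(x, y)
    return TrendResult(
        slope=float(res.slope),
        p_value=float(res.pvalue),
        r_squared=float(res.rvalue**2),
        n_species=len(points),
        level=levels.pop(),
        area_kind=area_kind,
        log_area=log_area,
    )


def area_trends(
    fits_by_level: Mapping[str, Iterable[PleFit]],
    species_areas: pd.DataFrame,
    log_area: bool = False,
) -> list[TrendResult]:
    """All level x area-kind trends (the 2D/3D cross-validation)."""
    out = []
    for level, fits in fits_by_level.items():
        fits = list(fits)
        for kind, col in (("A2", "A2_mm2"), ("A3", "A3_mm2")):
            areas = species_areas[col].to_dict()
            out.append(b_vs_area(fits, areas, area_kind=kind, log_area=log_area))
    return out


def rank_phyla(study: Study, taxonomy: Mapping[str, str]) -> pd.Series:
    """Phyla ranked by total abundance across all samples (ties broken by name)."""
    totals = study.table.counts.sum(axis=1)
    phylum = pd.Series({o: taxonomy.get(o) for o in study.table.otu_ids})
    grouped = totals.groupby(phylum).sum()
    order = sorted(grouped.index, key=lambda ph: (-grouped[ph], ph))
    return grouped.loc[order]


def dominant_phyla_fits(
    study: Study,
    taxonomy: Mapping[str, str],
    top_k: int = 6,
    ddof: int = 1,
) -> GroupedFits:
    """Type-I and Type-III fits restricted to each of the top_k most abundant
    phyla, labeled by phylum.  Unfittable phylum subsets are reported in
    ``failures``, not fatal.
    """
    ranked = rank_phyla(study, taxonomy)
    if len(ranked) < top_k:
        raise ValueError(f"taxonomy covers {len(ranked)} phyla, need >= top_k={top_k}")
    out = GroupedFits()
    for ph in ranked.index[:top_k]:
        otus = [o for o in study.table.otu_ids if taxonomy.get(o) == ph]
        sub = study.table.subset_otus(otus)
        for level, builder in (
            ("type_I", type1_mean_variance),
            ("type_III", type3_mean_variance),
        ):
            try:
                mv = builder(sub, group_label=str(ph), ddof=ddof)
                out.fits.append(fit_ple(mv))
            except InsufficientDataError as exc:
                out.failures[f"{ph}:{level}"] = str(exc)
    if not out.fits:
        raise InsufficientDataError(f"no phylum subset could be fitted: {out.failures}")
    return out


def trends_to_frame(trends: Iterable[TrendResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "level": t.level,
                "area_kind": t.area_kind,
                "log_area": t.log_area,
                "slope": t.slope,
                "p_value": t.p_value,
                "r2": t.r_squared,
                "n_species": t.n_species,
            }
            for t in trends
        ]
    )


def b_area_points(
    fits_by_level: Mapping[str, Iterable[PleFit]], species_areas: pd.DataFrame
) -> pd.DataFrame:
    """Long-form (species, level, area kind, b) table for plotting."""
    rows = []
    for level, fits in fits_by_level.items():
        for f in fits:
            if f.group_label not in species_areas.index:
                continue
            for kind, col in (("A2", "A2_mm2"), ("A3", "A3_mm2")):
                rows.append(
                    {
                        "host_species": f.group_label,
                        "level": f.level,
                        "area_kind": kind,
                        "area_mm2": species_areas.at[f.group_label, col],
                        "b": f.b,
                    }
                )
    return pd.DataFrame(rows)
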