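"""Taylor power-law extension (PLE) fitting for OTU tables.

Taylor's law relates the variance V of abundance to its mean M as
``V = a * M^b``; on log scale, ``ln V = ln a + b ln M``.  The slope b is the
heterogeneity scaling parameter: b < 1 indicates a uniform (regular) spatial
distribution, b = 1 a random one, and b > 1 aggregation.

Two community-level constructions are supported:

* **Type-I** — one (M, V) pair per sample: mean and variance are taken
  across all OTUs observed in that sample.  The slope b1 measures community
  spatial heterogeneity.
* **Type-III** — one (M, V) pair per OTU (the "mixed-species population"):
  mean and variance are taken across samples.  The slope b3 measures the
  spatial heterogeneity of conspecific populations pooled across hosts.

Zeros inside a unit's value vector count as abundance 0; only whole pairs
with M = 0 or V = 0 (log-undefined) are dropped before fitting, and the drop
count is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import OtuTable, Study

Level = Literal["type_I", "type_III"]
Basis = Literal["point_estimate", "ci_test"]

# b == 1 can only be meant exactly (e.g. hand-built fixtures); float noise
# otherwise makes the equality branch unreachable.
_B_EQUALITY_TOL = 1e-12


class InsufficientDataError(ValueError):
    def __init__(self, message: str, group_label: str = ""):
        super().__init__(message)
        self.group_label = group_label


@dataclass(frozen=True)
class MeanVariancePair:
    M: float
    V: float
    unit_id: str  # sample id (Type-I) or OTU id (Type-III)
    n_values: int


@dataclass
class MeanVarianceSet:
    level: Level
    group_label: str
    pairs: list[MeanVariancePair]
    n_dropped: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unit_id": [p.unit_id for p in self.pairs],
                "M": [p.M for p in self.pairs],
                "V": [p.V for p in self.pairs],
                "n_values": [p.n_values for p in self.pairs],
            }
        )


@dataclass(frozen=True)
class PleFit:
    level: Level
    group_label: str
    b: float
    ln_a: float
    r_squared: float
    b_ci: tuple[float, float]
    n_points: int
    p_value: float


@dataclass(frozen=True)
class HeterogeneityClass:
    category: Literal["uniform", "random", "aggregated"]
    basis: Basis


def _mean_variance(
    values: np.ndarray,
    unit_ids: Sequence[str],
    level: Level,
    group_label: str,
    ddof: int,
) -> MeanVarianceSet:
    """One (M, V) pair per row of ``values``; drop M=0 or V=0 pairs."""
    M = values.mean(axis=1)
    V = values.var(axis=1, ddof=ddof)
    pairs = []
    n_dropped = 0
    n = values.shape[1]
    for uid, m, v in zip(unit_ids, M, V):
        if m > 0 and v > 0:
            pairs.append(MeanVariancePair(M=float(m), V=float(v), unit_id=uid, n_values=n))
        else:
            n_dropped += 1
    return MeanVarianceSet(level=level, group_label=group_label, pairs=pairs, n_dropped=n_dropped)


def type1_mean_variance(
    table: OtuTable,
    sample_subset: Optional[Sequence[str]] = None,
    group_label: str = "all",
    ddof: int = 1,
) -> MeanVarianceSet:
    """Per-sample mean/variance across OTUs (community heterogeneity, Type-I)."""
    if sample_subset is not None:
        table = table.subset_samples(sample_subset)
    if table.n_otus < 2:
        raise InsufficientDataError(
            f"Type-I needs >= 2 OTUs for a variance, got {table.n_otus}", group_label
        )
    if table.n_samples < 1:
        raise InsufficientDataError("Type-I needs >= 1 sample", group_label)
    values = table.counts.to_numpy().T  # samples x OTUs
    return _mean_variance(values, table.sample_ids, "type_I", group_label, ddof)


def type3_mean_variance(
    table: OtuTable,
    sample_subset: Optional[Sequence[str]] = None,
    group_label: str = "all",
    ddof: int = 1,
    min_prevalence: int = 0,
) -> MeanVarianceSet:
    """Per-OTU mean/variance across samples (mixed-species populations, Type-III).

    ``min_prevalence`` optionally drops OTUs detected in fewer than that many
    samples before the mean/variance step (no filtering by default).
    """
    if sample_subset is not None:
        table = table.subset_samples(sample_subset)
    if table.n_samples < 2:
        raise InsufficientDataError(
            f"Type-III needs >= 2 samples for a variance, got {table.n_samples}", group_label
        )
    if table.n_otus < 1:
        raise InsufficientDataError("Type-III needs >= 1 OTU", group_label)
    values = table.counts.to_numpy()  # OTUs x samples
    otu_ids = table.otu_ids
    if min_prevalence > 0:
        keep = (values > 0).sum(axis=1) >= min_prevalence
        values = values[keep]
        otu_ids = [o for o, k in zip(otu_ids, keep) if k]
    return _mean_variance(values, otu_ids, "type_III", group_label, ddof)


def fit_ple(mv: MeanVarianceSet) -> PleFit:
    """OLS of ln V on ln M (natural log) with a t-based 95% CI for the slope."""
    n = len(mv.pairs)
    if n < 3:
        raise InsufficientDataError(
            f"group {mv.group_label!r}: {n} mean-variance pair(s) retained, need >= 3",
            mv.group_label,
        )
    ln_m = np.log([p.M for p in mv.pairs])
    ln_v = np.log([p.V for p in mv.pairs])
    res = stats.linregress(ln_m, ln_v)
    t_crit = stats.t.ppf(0.975, n - 2)
    ci = (res.slope - t_crit * res.stderr, res.slope + t_crit * res.stderr)
    return PleFit(
        level=mv.level,
        group_label=mv.group_label,
        b=float(res.slope),
        ln_a=float(res.intercept),
        r_squared=float(res.rvalue**2),
        b_ci=(float(ci[0]), float(ci[1])),
        n_points=n,
        p_value=float(res.pvalue),
    )


@dataclass
class GroupedFits:
    """Per-group fits plus the groups that could not be fitted and why."""

    fits: list[PleFit] = field(default_factory=list)
    failures: dict[str, str] = field(default_factory=dict)


def grouped_fits(
    study: Study,
    level: Level,
    group_by: Literal["all", "host_species"] = "all",
    ddof: int = 1,
    min_prevalence: int = 0,
) -> GroupedFits:
    """Fit the chosen PLE level overall or once per host species.

    Groups that fail the fit preconditions (too few samples/OTUs, or fewer
    than 3 log-transformable pairs) are reported in ``failures`` rather than
    silently skipped; all groups failing is an error.
    """
    if group_by == "all":
        groups = {"all": study.table.sample_ids}
    elif group_by == "host_species":
        groups = study.species_groups()
    else:
        raise ValueError(f"unknown group_by: {group_by!r}")
    out = GroupedFits()
    for label, samples in groups.items():
        try:
            if level == "type_I":
                mv = type1_mean_variance(study.table, samples, group_label=label, ddof=ddof)
            elif level == "type_III":
                mv = type3_mean_variance(
                    study.table, samples, group_label=label, ddof=ddof,
                    min_prevalence=min_prevalence,
                )
            else:
                raise ValueError(f"unknown level: {level!r}")
            out.fits.append(fit_ple(mv))
        except InsufficientDataError as exc:
            out.failures[label] = str(exc)
    if not out.fits:
        raise InsufficientDataError(
            f"no group could be fitted at {level}: {out.failures}", group_label=group_by
        )
    return out


def classify_heterogeneity(fit: PleFit, basis: Basis = "ci_test") -> HeterogeneityClass:
    """Classify spatial heterogeneity from the fitted slope.

    ``point_estimate``: b < 1 uniform, b = 1 random, b > 1 aggregated.
    ``ci_test``: aggregated only if the CI lower bound exceeds 1, uniform
    only if the upper bound is below 1, otherwise random (b = 1 not excluded).
    """
    if basis == "point_estimate":
        if abs(fit.b - 1.0) <= _B_EQUALITY_TOL:
            category = "random"
        elif fit.b > 1.0:
            category = "aggregated"
        else:
            category = "uniform"
    elif basis == "ci_test":
        lo, hi = fit.b_ci
        if lo > 1.0:
            category = "aggregated"
        elif hi < 1.0:
            category = "uniform"
        else:
            category = "random"
    else:
        raise ValueError(f"unknown basis: {basis!r}")
    return HeterogeneityClass(category=category, basis=basis)


def fits_to_frame(fits: Iterable[PleFit], basis: Basis = "ci_test") -> pd.DataFrame:
    """Tabulate fits for TSV output, including the heterogeneity class."""
    rows = []
    for f in fits:
        rows.append(
            {
                "group_label": f.group_label,
                "level": f.level,
                "n_points": f.n_points,
                "b": f.b,
                "b_ci_low": f.b_ci[0],
                "b_ci_high": f.b_ci[1],
                "ln_a": f.ln_a,
                "r2": f.r_squared,
                "p_value": f.p_value,
                "class": classify_heterogeneity(f, basis).category,
            }
        )
    return pd.DataFrame(rows)
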