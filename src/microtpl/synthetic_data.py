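"""Synthetic OTU tables, metadata and taxonomy with controlled
mean-variance scaling.

The generators target the Taylor law directly: each statistical unit (an
OTU for the Type-III construction, a sample for Type-I) gets a mean M drawn
from a log-uniform law, a variance pinned to V = exp(ln_a) * M^b, and its
abundances are then drawn i.i.d. from a distribution realizing that (M, V)
moment pair:

* ``power_law_gamma`` — gamma with shape M^2/V and scale V/M (any positive
  moment pair; continuous abundances, optionally rounded to counts);
* ``poisson`` — Poisson(M), so V = M and the fitted slope is 1 (the random
  / neutral null);
* ``negative_binomial`` — integer counts with V > M (overdispersed null).

``simulate_study`` assembles a multi-host-species study: per-species OTU
blocks (species-specific mean profiles, hence compositional shifts between
hosts), an optional shared core of OTUs with a common mean profile,
per-individual morphometric traits from truncated normals, and a phylum
assignment for every OTU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import OtuTable, SampleMetadata
from .morphometry import Morphometrics

Family = Literal["power_law_gamma", "poisson", "negative_binomial"]

#: Default phylum proportions for OTU taxonomy assignment: a composition
#: dominated by Proteobacteria and Bacteroidetes, as is typical of amphibian
#: skin communities.
DEFAULT_PHYLUM_PROPORTIONS: dict[str, float] = {
    "Proteobacteria": 0.30,
    "Bacteroidetes": 0.22,
    "Firmicutes": 0.14,
    "Actinobacteria": 0.12,
    "Acidobacteria": 0.07,
    "Verrucomicrobia": 0.06,
    "Cyanobacteria": 0.05,
    "Chloroflexi": 0.04,
}


class SimulationError(ValueError):
    """The spec requests an infeasible draw (moment pair or trait set)."""


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of one synthetic community.

    ``mean_law`` gives the log-uniform bounds [m_lo, m_hi] for unit means;
    the default spans two decades.  ``target_b``/``target_ln_a`` define the
    variance law V = exp(target_ln_a) * M^target_b (ignored for the poisson
    family, where V = M by construction).
    """

    n_samples: int
    n_otus: int
    target_b: float = 1.8
    target_ln_a: float = 0.0
    mean_law: tuple[float, float] = (1.0, 100.0)
    family: Family = "power_law_gamma"
    level_target: Literal["type_I", "type_III"] = "type_III"
    seed: Optional[int] = None
    integer_counts: bool = False

    def __post_init__(self) -> None:
        if self.n_samples < 3 or self.n_otus < 3:
            raise SimulationError("need n_samples >= 3 and n_otus >= 3")
        if self.mean_law[0] <= 0 or self.mean_law[1] < self.mean_law[0]:
            raise SimulationError(f"invalid mean_law bounds: {self.mean_law}")


@dataclass(frozen=True)
class SpeciesSpec:
    """One host species: sample count, trait law and its community law."""

    name: str
    n_individuals: int
    head_length_mm: tuple[float, float]  # (mean, sd)
    head_width_mm: tuple[float, float]
    body_length_mm: tuple[float, float]
    community: CommunitySpec


@dataclass(frozen=True)
class StudySpec:
    species: tuple[SpeciesSpec, ...]
    n_sites: int = 10
    n_shared_otus: int = 0
    seed: Optional[int] = None
    phylum_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHYLUM_PROPORTIONS)
    )

    def __post_init__(self) -> None:
        if len(self.species) < 1:
            raise SimulationError("need >= 1 species")
        for sp in self.species:
            for trait in (sp.head_length_mm, sp.head_width_mm, sp.body_length_mm):
                if trait[1] < 0:
                    raise SimulationError(f"{sp.name}: trait SD must be >= 0")


def _draw_unit_means(spec: CommunitySpec, n_units: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.mean_law
    return np.exp(rng.uniform(np.log(lo), np.log(hi), n_units))


def _draw_values(
    M: np.ndarray,
    spec: CommunitySpec,
    n_obs: int,
    rng: np.random.Generator,
    unit_prefix: str,
) -> np.ndarray:
    """Rows = units with target moments (M_u, V_u), columns = observations."""
    n_units = len(M)
    if spec.family == "poisson":
        return rng.poisson(M[:, None], size=(n_units, n_obs)).astype(float)
    V = np.exp(spec.target_ln_a) * M**spec.target_b
    bad = ~np.isfinite(V) | (V <= 0)
    if bad.any():
        u = int(np.argmax(bad))
        raise SimulationError(f"{unit_prefix}{u}: infeasible variance V={V[u]} for M={M[u]}")
    if spec.family == "power_law_gamma":
        shape = M**2 / V
        scale = V / M
        values = rng.gamma(shape[:, None], scale[:, None], size=(n_units, n_obs))
        if spec.integer_counts:
            values = np.rint(values)
        return values
    if spec.family == "negative_binomial":
        under = V <= M
        if under.any():
            u = int(np.argmax(under))
            raise SimulationError(
                f"{unit_prefix}{u}: negative_binomial needs V > M, got V={V[u]}, M={M[u]}"
            )
        r = M**2 / (V - M)
        p = M / V
        return rng.negative_binomial(r[:, None], p[:, None], size=(n_units, n_obs)).astype(float)
    raise SimulationError(f"unknown family: {spec.family!r}")


def _ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def simulate_mixed_population(
    spec: CommunitySpec, rng: Optional[np.random.Generator] = None
) -> OtuTable:
    """OTU table whose Type-III (per-OTU across-sample) fit targets b.

    Each OTU j gets a mean M_j from the log-uniform law and abundances drawn
    i.i.d. across samples with variance V_j = exp(ln_a) * M_j^b.
    """
    if spec.level_target != "type_III":
        raise SimulationError("simulate_mixed_population requires level_target='type_III'")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    M = _draw_unit_means(spec, spec.n_otus, rng)
    values = _draw_values(M, spec, spec.n_samples, rng, unit_prefix="OTU_")
    df = pd.DataFrame(values, index=_ids("OTU_", spec.n_otus), columns=_ids("S_", spec.n_samples))
    return OtuTable(df)


def simulate_community(
    spec: CommunitySpec, rng: Optional[np.random.Generator] = None
) -> OtuTable:
    """OTU table whose Type-I (per-sample across-OTU) fit targets b.

    Each sample i gets a community mean M_i and its OTU abundances are drawn
    i.i.d. with variance V_i = exp(ln_a) * M_i^b (poisson family: all OTUs
    in sample i are i.i.d. Poisson(M_i)).
    """
    if spec.level_target != "type_I":
        raise SimulationError("simulate_community requires level_target='type_I'")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    M = _draw_unit_means(spec, spec.n_samples, rng)
    values = _draw_values(M, spec, spec.n_otus, rng, unit_prefix="S_")
    df = pd.DataFrame(values.T, index=_ids("OTU_", spec.n_otus), columns=_ids("S_", spec.n_samples))
    return OtuTable(df)


def _draw_traits(
    sp: SpeciesSpec, rng: np.random.Generator, max_attempts: int = 1000
) -> Morphometrics:
    """Truncated-at-zero normal traits with h >= a enforced by resampling."""
    for _ in range(max_attempts):
        a = rng.normal(*sp.head_length_mm)
        b = rng.normal(*sp.head_width_mm)
        h = rng.normal(*sp.body_length_mm)
        if a > 0 and b > 0 and h > 0 and h >= a:
            return Morphometrics(a, b, h)
    raise SimulationError(
        f"{sp.name}: could not draw feasible traits (h >= a > 0) in {max_attempts} attempts; "
        "trait means/SDs are likely inconsistent"
    )


def simulate_study(
    spec: StudySpec,
) -> tuple[OtuTable, list[SampleMetadata], dict[str, str]]:
    """Full multi-species study: OTU table, per-sample metadata, taxonomy.

    Each species owns a block of OTUs with its own mean profile (composition
    shifts between hosts); ``n_shared_otus`` adds a core block whose mean
    profile is common to every species.  Abundances follow each species'
    community law; traits are drawn per individual; every OTU is assigned a
    phylum with the configured proportions.
    """
    rng = np.random.default_rng(spec.seed)
    names = [sp.name for sp in spec.species]
    if len(set(names)) != len(names):
        raise SimulationError(f"duplicate species names: {names}")

    n_core = spec.n_shared_otus
    core_ids = _ids("OTU_CORE_", n_core)
    block_ids = {
        sp.name: _ids(f"OTU_{si + 1:02d}_", sp.community.n_otus)
        for si, sp in enumerate(spec.species)
    }
    all_otus = core_ids + [o for sp in spec.species for o in block_ids[sp.name]]

    core_means = None
    if n_core:
        ref = spec.species[0].community
        lo, hi = ref.mean_law
        core_means = np.exp(rng.uniform(np.log(lo), np.log(hi), n_core))

    columns: dict[str, np.ndarray] = {}
    metadata: list[SampleMetadata] = []
    site_ids = [f"SITE_{i + 1:02d}" for i in range(spec.n_sites)]
    for sp in spec.species:
        cs = sp.community
        own_means = _draw_unit_means(cs, cs.n_otus, rng)
        own = _draw_values(own_means, cs, sp.n_individuals, rng, unit_prefix=f"{sp.name}:OTU_")
        if n_core:
            core = _draw_values(
                core_means, cs, sp.n_individuals, rng, unit_prefix=f"{sp.name}:CORE_"
            )
        sample_ids = [f"{sp.name}_{i + 1:03d}" for i in range(sp.n_individuals)]
        start = len(core_ids) + sum(
            spec.species[k].community.n_otus for k in range(names.index(sp.name))
        )
        for i, sid in enumerate(sample_ids):
            col = np.zeros(len(all_otus))
            if n_core:
                col[:n_core] = core[:, i]
            col[start : start + cs.n_otus] = own[:, i]
            columns[sid] = col
            metadata.append(
                SampleMetadata(
                    sample_id=sid,
                    host_species=sp.name,
                    site_id=site_ids[i % spec.n_sites],
                    morphometrics=_draw_traits(sp, rng),
                )
            )
    table = OtuTable(pd.DataFrame(columns, index=all_otus))

    phyla = list(spec.phylum_proportions)
    probs = np.array([spec.phylum_proportions[p] for p in phyla], dtype=float)
    probs = probs / probs.sum()
    taxonomy = dict(zip(all_otus, rng.choice(phyla, size=len(all_otus), p=probs)))
    return table, metadata, taxonomy


def default_study_spec(
    seed: Optional[int] = None,
    n_species: int = 10,
    total_samples: int = 358,
    otus_per_species: int = 300,
    n_shared_otus: int = 200,
    n_sites: int = 10,
    target_b: float = 1.8,
    target_ln_a: float = 0.0,
    mean_law: tuple[float, float] = (1.0, 100.0),
    family: Family = "power_law_gamma",
) -> StudySpec:
    """A study spec emulating a multi-site, ~10-species frog skin survey.

    Defaults: 358 samples split near-evenly over 10 host species sampled at
    10 sites, species-specific OTU blocks plus a shared core, an aggregated
    Type-III law (b = 1.8), and species mean body lengths spread from 35 to
    about 110 mm with head length ~0.32x and head width ~0.30x body length
    (SDs 8% of the mean), in the range of small-to-large anurans.
    """
    base, extra = divmod(total_samples, n_species)
    species = []
    for i in range(n_species):
        body = 35.0 + 75.0 * i / max(n_species - 1, 1)
        head_l, head_w = 0.32 * body, 0.30 * body
        species.append(
            SpeciesSpec(
                name=f"Species_{i + 1:02d}",
                n_individuals=base + (1 if i < extra else 0),
                head_length_mm=(head_l, 0.08 * head_l),
                head_width_mm=(head_w, 0.08 * head_w),
                body_length_mm=(body, 0.08 * body),
                community=CommunitySpec(
                    n_samples=base + (1 if i < extra else 0),
                    n_otus=otus_per_species,
                    target_b=target_b,
                    target_ln_a=target_ln_a,
                    mean_law=mean_law,
                    family=family,
                    level_target="type_III",
                ),
            )
        )
    return StudySpec(
        species=tuple(species), n_sites=n_sites, n_shared_otus=n_shared_otus, seed=seed
    )
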