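"""Equivalent-geometry skin surface area models for anuran hosts.

A frog body is idealized as a cone (the head: base diameter = head width
``b``, height = head length ``a``) sitting on a cylinder (the trunk: diameter
``b``, height ``h - a`` where ``h`` is body length).  The 3D skin area is the
lateral cone surface plus the lateral cylinder surface plus the single
posterior base disc:

    A3 = (pi*b/2) * sqrt(a^2 + b^2/4) + pi*b*(h - a) + pi*b^2/4

The 2D counterpart is the flat silhouette, a triangle head plus a rectangle
trunk:

    A2 = a*b/2 + b*(h - a)

Limbs are deliberately omitted.  All traits are in millimetres, areas in
mm^2; the formulas themselves are unit-agnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd


class MorphometryError(ValueError):
    """Trait values outside the geometric model's domain."""


@dataclass(frozen=True)
class Morphometrics:
    """Per-individual traits: head length a, head width b, body length h (mm)."""

    head_length_mm: float
    head_width_mm: float
    body_length_mm: float

    def __post_init__(self) -> None:
        a, b, h = self.head_length_mm, self.head_width_mm, self.body_length_mm
        if a < 0 or b < 0:
            raise MorphometryError(f"negative trait: a={a}, b={b}")
        if h < a:
            raise MorphometryError(
                f"body length ({h}) must be >= head length ({a}): cylinder height h-a < 0"
            )


def _traits(m, b=None, h=None) -> tuple[float, float, float]:
    # accept either a Morphometrics or three bare (a, b, h) floats
    if isinstance(m, Morphometrics):
        return m.head_length_mm, m.head_width_mm, m.body_length_mm
    if b is None or h is None:
        raise TypeError("pass a Morphometrics or three trait values (a, b, h)")
    Morphometrics(m, b, h)  # validate
    return float(m), float(b), float(h)


def skin_area_3d(m, b: float | None = None, h: float | None = None) -> float:
    """3D skin area (mm^2): cone lateral + cylinder lateral + one base disc."""
    a, w, length = _traits(m, b, h)
    slant = math.sqrt(a**2 + w**2 / 4.0)
    cone = math.pi * w / 2.0 * slant
    cylinder = math.pi * w * (length - a)
    disc = math.pi * w**2 / 4.0
    return cone + cylinder + disc


def skin_area_2d(m, b: float | None = None, h: float | None = None) -> float:
    """2D silhouette area (mm^2): triangle head + rectangle trunk."""
    a, w, length = _traits(m, b, h)
    return a * w / 2.0 + w * (length - a)


def compute_areas(metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-sample A2/A3 from a joined-study metadata frame.

    Expects columns head_length_mm, head_width_mm, body_length_mm (and
    host_species, which is carried through); returns a frame indexed by
    sample id with host_species, A2_mm2, A3_mm2.
    """
    rows = {}
    for sid, row in metadata.iterrows():
        m = Morphometrics(row["head_length_mm"], row["head_width_mm"], row["body_length_mm"])
        rows[sid] = {
            "host_species": row["host_species"],
            "A2_mm2": skin_area_2d(m),
            "A3_mm2": skin_area_3d(m),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


def species_mean_area(areas: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean A2/A3 per host species.

    ``areas`` is the output of :func:`compute_areas`.  Each species group is
    non-empty by construction; an empty input is an error.
    """
    if len(areas) == 0:
        raise MorphometryError("no individuals: species mean area undefined")
    grouped = areas.groupby("host_species")[["A2_mm2", "A3_mm2"]].mean()
    grouped["n_individuals"] = areas.groupby("host_species").size()
    grouped.index.name = "host_species"
    return grouped
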