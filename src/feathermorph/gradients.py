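"""Prescribed spatial profiles for graded quantities.

CYP26B1 concentration and the CRABP1 / WNT maximum production rates are
spatially dependent inputs of the regulatory model.  Each is described by a
scaling coefficient ``a`` (the amplitude) and a slope parameter ``v``:

* ``anterior_posterior`` profiles are functions of the circumferential
  distance d(x) = min(|x|, 1 - |x|) from the anterior midline, hence
  continuous on the circle:  a * exp(v * d(x)).
* ``lateral_medial`` profiles are monotone across the vanes,
  a * exp(v * (x - 0.5)), continuous at the posterior midline and wrapping
  discontinuously only at x = 0, inside the rachis zone where branching is
  suppressed.

``v = 0`` reduces either form to the constant profile of height ``a``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import SpatialGrid

AXES = ("anterior_posterior", "lateral_medial")
FORMS = ("exponential", "constant")


@dataclass(frozen=True)
class GradientSpec:
    """Amplitude/slope description of a graded concentration or rate."""

    a: float
    v: float = 0.0
    axis: str = "lateral_medial"
    form: str = "exponential"

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError(f"gradient amplitude must be >= 0, got {self.a}")
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}, got {self.axis!r}")
        if self.form not in FORMS:
            raise ValueError(f"form must be one of {FORMS}, got {self.form!r}")


def build_gradient(spec: GradientSpec, grid: SpatialGrid) -> np.ndarray:
    """Evaluate a gradient specification on the grid.

    Returns a non-negative profile of length ``grid.n_points``.
    """
    if spec.form == "constant" or spec.v == 0.0:
        return np.full(grid.n_points, spec.a, dtype=float)
    if spec.axis == "anterior_posterior":
        arg = grid.circumferential_distance()
    else:
        arg = grid.x - 0.5
    return spec.a * np.exp(spec.v * arg)
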