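"""Periodic 1-D circumferential grid.

The feather epithelial cylinder is unrolled onto the circle x in [0, 1).
By convention x = 0 is the anterior (rachis) midline and x = 0.5 the
posterior midline where the barb generative zone (BGZ) sits; the lateral
vane occupies (0, 0.5) and the medial vane (0.5, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class SpatialGrid:
    """Uniform periodic grid on the unit circle.

    Parameters
    ----------
    n_points
        Number of spatial nodes (>= 16). Node i sits at x = i / n_points;
        the wrap-around neighbour of the last node is the first node.
    """

    n_points: int
    x: np.ndarray = field(init=False, repr=False, compare=False)
    dx: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_points < 16:
            raise ValueError(f"n_points must be >= 16, got {self.n_points}")
        object.__setattr__(self, "dx", 1.0 / self.n_points)
        object.__setattr__(
            self, "x", np.arange(self.n_points, dtype=float) * self.dx
        )

    def laplacian(self, f: np.ndarray) -> np.ndarray:
        """Second-order central-difference Laplacian with periodic wrap."""
        return (np.roll(f, -1) + np.roll(f, 1) - 2.0 * f) / self.dx**2

    def circumferential_distance(self) -> np.ndarray:
        """Distance d(x) = min(|x|, 1 - |x|) from the anterior midline.

        Continuous on the circle; ranges over [0, 0.5] with the maximum at
        the posterior midline.
        """
        return np.minimum(self.x, 1.0 - self.x)


def total_mass(f: np.ndarray, grid: SpatialGrid) -> float:
    """Integral of a nodal field over the circle (sum times dx)."""
    return float(np.sum(f) * grid.dx)
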