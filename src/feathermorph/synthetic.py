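"""Synthetic inputs with known ground truth.

Every generator takes an explicit seed and is bit-reproducible; the
imposed ground truth (wave speed, lattice stretch, planted screen
verdicts) is returned alongside the data so downstream estimators can be
validated against construction rather than against themselves.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box

from .grid import SpatialGrid
from .pb import Kymograph
from .screen import ExpressionTable, GROUPS
from .tortuosity import CellMesh


def synthetic_kymograph(
    wavelength: float,
    speed: float,
    duration: float,
    grid: SpatialGrid,
    dt_record: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Kymograph:
    """Travelling sine wave A(x, t) = sin(2 pi (x - speed t)/wavelength).

    The wavelength must divide the unit circumference an integer number of
    times (periodic domain; avoids spectral leakage in fixtures).
    """
    n_waves = 1.0 / wavelength
    if abs(n_waves - round(n_waves)) > 1e-9:
        raise ValueError(
            f"wavelength {wavelength} must fit the domain an integer "
            "number of times"
        )
    times = np.arange(0.0, duration + 0.5 * dt_record, dt_record)
    rng = np.random.default_rng(seed)
    phase = 2 * np.pi * (grid.x[None, :] - speed * times[:, None]) / wavelength
    A = np.sin(phase)
    if noise_sd > 0:
        A = A + noise_sd * rng.standard_normal(A.shape)
    meta = {
        "generator": "synthetic_kymograph",
        "wavelength": wavelength,
        "speed": speed,
        "frequency": abs(speed) / wavelength,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return Kymograph(A_xt=A, times=times, dt=dt_record, dx=grid.dx,
                     metadata=meta)


def generate_cell_lattice(
    n_cells: int,
    stretch: float = 1.0,
    seed: int = 0,
    jitter: float = 0.1,
) -> CellMesh:
    """Anisotropic epithelial lattice: jittered-grid Voronoi tessellation.

    Seed points sit on a square grid in the unit box with uniform jitter,
    then the domain is scaled by ``stretch`` along y, elongating cells in
    the proximal-distal direction.  Mean cell aspect ratio grows with
    ``stretch``; stretch 1 is the isotropic control.
    """
    if n_cells < 4:
        raise ValueError("need at least 4 cells")
    if stretch < 1:
        raise ValueError("stretch must be >= 1")
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n_cells)))
    gx, gy = np.meshgrid(
        (np.arange(side) + 0.5) / side, (np.arange(side) + 0.5) / side
    )
    pts = np.column_stack([gx.ravel(), gy.ravel()])[:n_cells]
    for attempt in range(3):
        pert = pts + (jitter / side) * rng.uniform(-1, 1, pts.shape)
        pert[:, 1] *= stretch
        # mirror seeds across each wall so boundary cells close cleanly
        left = np.column_stack([-pert[:, 0], pert[:, 1]])
        right = np.column_stack([2.0 - pert[:, 0], pert[:, 1]])
        bottom = np.column_stack([pert[:, 0], -pert[:, 1]])
        top = np.column_stack([pert[:, 0], 2.0 * stretch - pert[:, 1]])
        allpts = np.vstack([pert, left, right, bottom, top])
        try:
            vor = Voronoi(allpts)
        except Exception:
            continue
        domain = box(0.0, 0.0, 1.0, stretch)
        polys = []
        ok = True
        for i in range(len(pert)):
            region = vor.regions[vor.point_region[i]]
            if -1 in region or len(region) < 3:
                ok = False
                break
            poly = Polygon(vor.vertices[region]).intersection(domain)
            if poly.is_empty or poly.geom_type != "Polygon":
                ok = False
                break
            polys.append(poly)
        if ok:
            return CellMesh.from_polygons(polys)
    raise RuntimeError("degenerate point set; could not build a Voronoi mesh")


def generate_expression_table(
    n_genes: int = 50,
    n_planted_pass: int = 7,
    effect_fc: float = 3.0,
    seed: int = 0,
    fc_min: float = 1.8,
    tpm_min: float = 25.0,
) -> tuple[ExpressionTable, pd.Series]:
    """Two-group, two-replicate TPM table with planted screen outcomes.

    Planted passes satisfy all three filter conditions by construction;
    the remaining genes cycle through the three single-failure modes
    (sub-threshold fold change, sub-threshold abundance, inconsistent
    replicate direction).  Returns the table and a boolean ground-truth
    series indexed by gene.
    """
    if n_planted_pass > n_genes:
        raise ValueError("more planted passes than genes")
    if effect_fc <= fc_min:
        raise ValueError(f"planted effect_fc must exceed {fc_min}")
    rng = np.random.default_rng(seed)
    genes = [f"gene_{i:04d}" for i in range(n_genes)]
    truth = pd.Series(False, index=genes)
    rows = {}
    rep_noise = 0.03   # antisymmetric scatter: group means stay exact

    def reps(mean):
        d = rep_noise * rng.uniform(0.2, 1.0)
        return mean * np.array([1 + d, 1 - d])

    for i, g in enumerate(genes):
        if i < n_planted_pass:
            lo = rng.uniform(2 * tpm_min, 4 * tpm_min)
            hi = lo * effect_fc   # group-mean ratio exactly effect_fc
            up = rng.random() < 0.5
            a, b = (lo, hi) if up else (hi, lo)
            rows[g] = np.concatenate([reps(a), reps(b)])
            truth[g] = True
        else:
            mode = (i - n_planted_pass) % 3
            if mode == 0:     # fold change too small, all else fine
                lo = rng.uniform(2 * tpm_min, 4 * tpm_min)
                hi = lo * rng.uniform(1.1, min(fc_min, 1.7))
                rows[g] = np.concatenate([reps(lo), reps(hi)])
            elif mode == 1:   # abundant-group mean too low, fc fine
                lo = rng.uniform(1.0, 4.0)
                hi = min(lo * effect_fc, tpm_min * 0.8)
                rows[g] = np.concatenate([reps(lo), reps(hi)])
            else:             # one replicate pair flips direction
                lo = rng.uniform(2 * tpm_min, 4 * tpm_min)
                hi = lo * max(effect_fc, 3.0)
                rows[g] = np.concatenate(
                    [[lo, lo], [hi, 0.9 * lo]]
                )
    samples = ["narrow_1", "narrow_2", "wide_1", "wide_2"]
    values = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    sheet = pd.DataFrame(
        {
            "sample": samples,
            "group": [GROUPS[0], GROUPS[0], GROUPS[1], GROUPS[1]],
            "replicate": [1, 2, 1, 2],
        }
    )
    return ExpressionTable(values=values, sample_sheet=sheet), truth
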