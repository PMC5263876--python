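"""Feather-geometry analyses of kymographs and steady profiles.

Barbs grow helically: an activator peak travelling circumferentially at
speed W while the feather elongates at rate V traces a helix whose angle
to the proximal-distal axis is theta = arctan(W / V).  The mature
barb-rachis angle adds the expansion angle beta gained when the feather
web opens, a material property supplied as configuration.

Zone classification reads the steady regulatory profiles: the rachis is
the contiguous GDF10-high zone around the anterior midline, the barb
generative zone (BGZ) the contiguous GREM1-high zone around the GREM1
maximum, and the remainder is vane (lateral arc between rachis and BGZ on
the x < 0.5 side, medial on the other).  The asymmetry index
(medial - lateral) / (medial + lateral) of the vane widths quantifies
bilateral vane asymmetry; 0 for symmetric plumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .grid import SpatialGrid
from .mrf import SteadyState
from .pb import Kymograph


class DegeneratePatternError(RuntimeError):
    """No spectral peak above the noise floor; the pattern has no period."""


class ZoneConfigurationError(RuntimeError):
    """Zone thresholds produce overlapping rachis and BGZ zones."""


@dataclass(frozen=True)
class WaveStatistics:
    """Travelling-wave summary of a kymograph zone."""

    wavelength: float          # mean spatial period, circumference units
    frequency: float           # mean temporal frequency at fixed x
    speed_W: float             # wavelength * frequency
    side: str = "lateral"
    direction: float = 0.0     # sign of phase drift (+: toward larger x)
    quality_warning: str | None = None

    def __post_init__(self) -> None:
        if not np.isclose(self.speed_W, self.wavelength * self.frequency):
            raise ValueError("speed_W must equal wavelength * frequency")


@dataclass
class ZoneMap:
    """Per-node zone labels plus derived widths (circumference units)."""

    labels: np.ndarray         # strings: rachis | vane_lateral | vane_medial | BGZ
    rachis_width: float
    bgz_width: float
    vane_lateral_width: float
    vane_medial_width: float

    @property
    def asymmetry_index(self) -> float:
        tot = self.vane_medial_width + self.vane_lateral_width
        if tot == 0:
            return 0.0
        return (self.vane_medial_width - self.vane_lateral_width) / tot

    @property
    def total_vane_width(self) -> float:
        return self.vane_lateral_width + self.vane_medial_width


@dataclass
class VaneGeometry:
    """Derived feather geometry for one simulated cross-section."""

    theta_lateral: float       # helical growth angle, degrees
    theta_medial: float
    beta_expand: float         # expansion angle after maturation, degrees
    elongation_V: float
    zone_map: ZoneMap

    @property
    def barb_rachis_angle_lateral(self) -> float:
        return self.theta_lateral + self.beta_expand

    @property
    def barb_rachis_angle_medial(self) -> float:
        return self.theta_medial + self.beta_expand

    @property
    def asymmetry_index(self) -> float:
        return self.zone_map.asymmetry_index

    def barb_length(self, side: str) -> float:
        """Vane arc width / sin(barb-rachis angle), per the helical sketch."""
        if side == "lateral":
            w, ang = self.zone_map.vane_lateral_width, self.barb_rachis_angle_lateral
        else:
            w, ang = self.zone_map.vane_medial_width, self.barb_rachis_angle_medial
        s = np.sin(np.deg2rad(ang))
        return float(w / s) if s > 0 else float("inf")


@dataclass
class FeatherSilhouette:
    """Renderable feather outline with barb segments."""

    outline: np.ndarray                    # closed polygon, shape (n, 2)
    barbs_lateral: list[np.ndarray] = field(default_factory=list)
    barbs_medial: list[np.ndarray] = field(default_factory=list)
    rachis: np.ndarray | None = None       # centreline, shape (m, 2)


def _dominant_peak(freqs: np.ndarray, power: np.ndarray,
                   noise_floor_ratio: float = 5.0) -> float:
    """Dominant non-DC spectral peak with parabolic interpolation.

    Raises :class:`DegeneratePatternError` when the peak does not rise
    above ``noise_floor_ratio`` times the median non-DC power.
    """
    p = power.copy()
    p[0] = 0.0
    i = int(np.argmax(p))
    if i == 0 or p[i] <= 0:
        raise DegeneratePatternError("flat spectrum")
    floor = np.median(p[1:][p[1:] > 0]) if np.any(p[1:] > 0) else 0.0
    if floor > 0 and p[i] < noise_floor_ratio * floor:
        raise DegeneratePatternError(
            f"dominant peak only {p[i] / floor:.1f}x the noise floor"
        )
    if 0 < i < len(p) - 1 and p[i - 1] > 0 and p[i + 1] > 0:
        la, lb, lc = np.log(p[i - 1]), np.log(p[i]), np.log(p[i + 1])
        denom = la - 2 * lb + lc
        delta = 0.5 * (la - lc) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    df = freqs[1] - freqs[0]
    return float(freqs[i] + delta * df)


def estimate_wave_speed(
    kymo: Kymograph,
    zone: np.ndarray | slice | None = None,
    time_window: float | None = None,
    side: str = "lateral",
    stationary_tol: float = 1e-3,
) -> WaveStatistics:
    """Wave speed = mean spatial wavelength x mean temporal frequency.

    The wavelength comes from the dominant peak of Hann-windowed spatial
    periodograms averaged over the analysis window; the frequency from
    temporal periodograms at the zone's central nodes.  A phase-drift
    cross-check (slope of the space-time spectral ridge) must agree with
    the product within 10% or a quality warning is attached.

    ``time_window``: length of the trailing time interval analysed
    (defaults to the second half of the record).
    """
    A = kymo.A_xt
    if zone is None:
        zone = np.arange(A.shape[1])
    elif isinstance(zone, slice):
        zone = np.arange(A.shape[1])[zone]
    zone = np.asarray(zone)
    times = kymo.times
    if time_window is None:
        t0 = times[-1] - (times[-1] - times[0]) / 2.0
    else:
        t0 = times[-1] - time_window
    rows = np.nonzero(times >= t0)[0]
    sub = A[np.ix_(rows, zone)]
    dt_rec = float(times[1] - times[0]) if len(times) > 1 else kymo.dt

    # spatial wavelength over the zone
    f_x, p_x = signal.periodogram(
        sub - sub.mean(axis=1, keepdims=True), fs=1.0 / kymo.dx,
        window="hann", axis=1, detrend=False,
    )
    wavelength = 1.0 / _dominant_peak(f_x, p_x.mean(axis=0))

    # temporal frequency at the central nodes
    centre = zone[len(zone) // 2]
    picks = [c for c in (centre - 1, centre, centre + 1) if c in zone]
    traces = A[np.ix_(rows, np.asarray(picks))]
    f_t, p_t = signal.periodogram(
        traces - traces.mean(axis=0, keepdims=True), fs=1.0 / dt_rec,
        window="hann", axis=0, detrend=False,
    )
    pw_t = p_t.mean(axis=1)
    temporal_amp = float(traces.std(axis=0).mean())
    spatial_amp = float(sub.std())
    if spatial_amp > 0 and temporal_amp < stationary_tol * spatial_amp:
        frequency = 0.0   # stationary stripes
    else:
        try:
            frequency = _dominant_peak(f_t, pw_t)
        except DegeneratePatternError:
            frequency = 0.0
    speed = wavelength * frequency

    # cross-check: phase drift of the dominant spatial mode
    direction = 0.0
    quality = None
    if frequency > 0:
        n_zone = len(zone)
        fft_rows = np.fft.rfft(sub - sub.mean(axis=1, keepdims=True), axis=1)
        kdom = int(np.argmax(np.abs(fft_rows[0, 1:]))) + 1
        phases = np.unwrap(np.angle(fft_rows[:, kdom]))
        slope = np.polyfit(np.arange(len(phases)), phases, 1)[0]
        # phase decreases as the pattern moves toward +x
        speed_ridge = -slope / dt_rec / (2 * np.pi * kdom / (n_zone * kymo.dx))
        direction = float(np.sign(speed_ridge))
        if speed > 0 and abs(abs(speed_ridge) - speed) > 0.10 * speed:
            quality = (
                f"ridge-slope speed {abs(speed_ridge):.4g} deviates >10% "
                f"from spectral product {speed:.4g}"
            )
            warnings.warn(quality, stacklevel=2)
    return WaveStatistics(
        wavelength=wavelength, frequency=frequency, speed_W=speed,
        side=side, direction=direction, quality_warning=quality,
    )


def helical_angle(speed_W: float | WaveStatistics,
                  elongation_V: float) -> float:
    """theta = arctan(W / V) in degrees."""
    if isinstance(speed_W, WaveStatistics):
        speed_W = speed_W.speed_W
    if elongation_V <= 0:
        raise ValueError("elongation rate must be positive")
    return float(np.degrees(np.arctan2(abs(speed_W), elongation_V)))


def _contiguous_zone(mask: np.ndarray, anchor: int) -> np.ndarray:
    """Indices of the contiguous True run containing ``anchor`` on the
    periodic index circle; empty if mask[anchor] is False."""
    n = len(mask)
    if not mask[anchor]:
        return np.array([], dtype=int)
    idx = [anchor]
    i = (anchor + 1) % n
    while mask[i] and i != anchor:
        idx.append(i)
        i = (i + 1) % n
    i = (anchor - 1) % n
    while mask[i] and i not in (anchor, idx[-1]):
        idx.insert(0, i)
        i = (i - 1) % n
    return np.unique(np.array(idx, dtype=int))


def classify_zones(
    mrf: SteadyState,
    grid: SpatialGrid,
    grem_threshold: float | str = "auto",
    gdf_threshold: float | str = "auto",
) -> ZoneMap:
    """Per-node zone labels from the steady GDF10 and GREM1 profiles.

    Thresholds are absolute concentrations; ``"auto"`` uses 50% of the
    profile's own dynamic range.  The rachis zone is anchored at the
    anterior midline, the BGZ at the GREM1 maximum; each is the contiguous
    super-threshold run around its anchor.
    """
    gdf = mrf.profile("GDF")
    grem = mrf.profile("GREM")
    n = grid.n_points
    if gdf_threshold == "auto":
        gdf_threshold = gdf.min() + 0.5 * (gdf.max() - gdf.min())
    if grem_threshold == "auto":
        grem_threshold = grem.min() + 0.5 * (grem.max() - grem.min())

    rachis_idx = _contiguous_zone(gdf > gdf_threshold, 0)
    grem_anchor = int(np.argmax(grem))
    bgz_idx = _contiguous_zone(grem > grem_threshold, grem_anchor)
    if np.intersect1d(rachis_idx, bgz_idx).size:
        raise ZoneConfigurationError(
            "rachis and BGZ zones overlap; thresholds are inconsistent"
        )
    labels = np.empty(n, dtype=object)
    labels[:] = "vane_lateral"
    labels[rachis_idx] = "rachis"
    labels[bgz_idx] = "BGZ"

    # vane arcs: lateral from rachis end forward to BGZ start, medial back
    vane_mask = (labels != "rachis") & (labels != "BGZ")
    if bgz_idx.size:
        for i in np.nonzero(vane_mask)[0]:
            # walk forward from i; hitting BGZ first => lateral side
            j = i
            while vane_mask[j]:
                j = (j + 1) % n
            labels[i] = "vane_lateral" if labels[j] == "BGZ" else "vane_medial"
    else:
        labels[vane_mask & (grid.x >= 0.5)] = "vane_medial"

    dx = grid.dx
    return ZoneMap(
        labels=labels,
        rachis_width=float(np.sum(labels == "rachis") * dx),
        bgz_width=float(np.sum(labels == "BGZ") * dx),
        vane_lateral_width=float(np.sum(labels == "vane_lateral") * dx),
        vane_medial_width=float(np.sum(labels == "vane_medial") * dx),
    )


def cell_shape_modifiers(
    rar_signal: np.ndarray | float,
    rho_max: float = 3.0,
    k_rho: float = 0.2,
    n_rho: float = 2.0,
    tortuosity_slope: float = 0.2,
) -> tuple[float, float, float]:
    """Map a mean RA signal to (aspect ratio, V multiplier, D_A multiplier).

    Low RA elongates epithelial cells: rho(RAR) decreases from ``rho_max``
    to 1 as the signal rises.  Elongation speeds feather outgrowth (V
    multiplier proportional to rho) and raises tissue tortuosity
    lambda(rho) = 1 + slope*(rho - 1), cutting the apparent activator
    diffusivity by 1/lambda^2.  Both multipliers are exactly 1 at rho = 1.
    """
    rar = float(np.mean(rar_signal))
    rho = 1.0 + (rho_max - 1.0) * k_rho**n_rho / (k_rho**n_rho + max(rar, 0.0)**n_rho)
    lam = 1.0 + tortuosity_slope * (rho - 1.0)
    return rho, rho, 1.0 / lam**2


def aspect_ratio_modifiers(
    rho: float,
    tortuosity_of_stretch=None,
) -> tuple[float, float]:
    """(V multiplier, D_A multiplier) for a given cell aspect ratio.

    ``tortuosity_of_stretch``: callable lambda(rho), e.g. the curve fitted
    on synthetic lattices by the tortuosity module; identity-consistent
    (lambda(1) = 1) curves give multipliers (1, 1) at rho = 1.
    """
    if rho < 1:
        raise ValueError("aspect ratio must be >= 1")
    lam = 1.0 if tortuosity_of_stretch is None else float(tortuosity_of_stretch(rho))
    if rho == 1.0:
        return 1.0, 1.0
    return float(rho), 1.0 / lam**2


def render_silhouette(
    geometry: VaneGeometry,
    length: float = 1.0,
    n_slices: int = 40,
    zone_maps: list[ZoneMap] | None = None,
) -> FeatherSilhouette:
    """Feather outline from per-slice vane widths and barb-rachis angles.

    Each proximal-distal slice z = V t projects its vane arc width onto
    the feather plane through sin(barb-rachis angle); barb segments are
    drawn at that angle.  ``zone_maps`` (one per slice) override the
    geometry's single zone map, enabling piecewise perturbations.
    """
    if n_slices < 2:
        raise ValueError("need at least 2 slices")
    if zone_maps is not None and len(zone_maps) != n_slices:
        raise ValueError("zone_maps must have one entry per slice")
    if zone_maps is None:
        zone_maps = [geometry.zone_map] * n_slices
    if all(zm.total_vane_width == 0 for zm in zone_maps):
        raise ValueError("empty zone map: no vane to render")

    z = np.linspace(0.0, length, n_slices)
    ang_l = np.deg2rad(geometry.barb_rachis_angle_lateral)
    ang_m = np.deg2rad(geometry.barb_rachis_angle_medial)
    half_l = np.array([zm.vane_lateral_width * np.sin(ang_l) for zm in zone_maps])
    half_m = np.array([zm.vane_medial_width * np.sin(ang_m) for zm in zone_maps])

    left = np.column_stack([-half_l, z])       # lateral on -y
    right = np.column_stack([half_m, z])
    outline = np.vstack([right, left[::-1], right[:1]])

    barbs_l, barbs_m = [], []
    for zi, hl, hm in zip(z, half_l, half_m):
        if hl > 0 and np.sin(ang_l) > 0:
            run = hl / np.tan(ang_l) if np.tan(ang_l) > 0 else 0.0
            barbs_l.append(np.array([[0.0, zi], [-hl, min(zi + run, length)]]))
        if hm > 0 and np.sin(ang_m) > 0:
            run = hm / np.tan(ang_m) if np.tan(ang_m) > 0 else 0.0
            barbs_m.append(np.array([[0.0, zi], [hm, min(zi + run, length)]]))
    rachis = np.column_stack([np.zeros_like(z), z])
    return FeatherSilhouette(
        outline=outline, barbs_lateral=barbs_l, barbs_medial=barbs_m,
        rachis=rachis,
    )


def silhouette_half_areas(sil: FeatherSilhouette) -> tuple[float, float]:
    """(lateral, medial) half-areas of the outline via the shoelace rule."""
    from shapely.geometry import Polygon

    poly = Polygon(sil.outline)
    if not poly.is_valid:
        raise ValueError("outline polygon is not simple")
    minx, miny, maxx, maxy = poly.bounds
    from shapely.geometry import box

    lat = poly.intersection(box(minx - 1, miny - 1, 0.0, maxy + 1)).area
    med = poly.intersection(box(0.0, miny - 1, maxx + 1, maxy + 1)).area
    return float(lat), float(med)
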