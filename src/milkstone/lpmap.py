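"""Lactase-persistence phenotype-frequency surfaces.

Converts combined causal-allele frequencies (the five known lactase
enhancer variants -13907*G, -13910*T, -13915*G, -14009*G, -14010*C are
treated as allelic at one locus) to phenotype frequencies under dominant
inheritance and Hardy-Weinberg, then interpolates a sample-size-weighted
Gaussian-kernel (Nadaraya-Watson) surface on a regular lon/lat grid.
Distances are planar degrees, a known distortion at high latitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class LPPoint:
    latitude: float
    longitude: float
    allele_freq: float  # combined causal-allele frequency p in [0, 1]
    sample_size: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.allele_freq <= 1.0):
            raise ValueError(f"allele_freq {self.allele_freq} outside [0, 1]")
        if not (-90.0 <= self.latitude <= 90.0):
            raise ValueError(f"latitude {self.latitude} out of range")
        if not (-180.0 <= self.longitude <= 360.0):
            raise ValueError(f"longitude {self.longitude} out of range")
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")


@dataclass
class GridSpec:
    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    n_lon: int = 60
    n_lat: int = 60

    def lattice(self) -> tuple[np.ndarray, np.ndarray]:
        lons = np.linspace(self.lon_min, self.lon_max, self.n_lon)
        lats = np.linspace(self.lat_min, self.lat_max, self.n_lat)
        return lons, lats


@dataclass
class LPSurface:
    grid: GridSpec
    values: np.ndarray  # (n_lat, n_lon) phenotype frequency
    reliable: np.ndarray  # same shape; False where kernel mass below floor
    sigma: float
    mass_floor: float = 1e-6
    points: list[LPPoint] = field(default_factory=list)


def phenotype_freq(p: float | np.ndarray) -> float | np.ndarray:
    """Phenotype frequency under dominance: 1 - (1-p)^2."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("allele frequency outside [0, 1]")
    out = 1.0 - (1.0 - arr) ** 2
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def _kernel_weights(
    points: Sequence[LPPoint], grid: GridSpec, sigma: float
) -> tuple[np.ndarray, np.ndarray]:
    """(n_cells, n_points) weighted kernel matrix and point frequencies."""
    lons, lats = grid.lattice()
    glon, glat = np.meshgrid(lons, lats)
    cells = np.column_stack([glon.ravel(), glat.ravel()])
    pts = np.array([[p.longitude, p.latitude] for p in points])
    w = np.array([float(p.sample_size) for p in points])
    d2 = ((cells[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    k = w[None, :] * np.exp(-d2 / (2.0 * sigma**2))
    f = phenotype_freq(np.array([p.allele_freq for p in points]))
    return k, np.asarray(f, dtype=float)


def smooth_surface(
    points: Sequence[LPPoint],
    sigma: float,
    grid: GridSpec,
    mass_floor: float = 1e-6,
) -> LPSurface:
    """Sample-size-weighted Nadaraya-Watson smoothing of phenotype
    frequencies on the grid.

    value(cell) = sum_i w_i K(d_i/sigma) f_i / sum_i w_i K(d_i/sigma) with a
    Gaussian kernel. Cells whose relative kernel mass (against total weight)
    falls below ``mass_floor`` are flagged unreliable; their value is still
    the ratio (never NaN) unless the mass underflows entirely, in which case
    the nearest point's frequency is used.
    """
    if not points:
        raise ValueError("need at least one point")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    k, f = _kernel_weights(points, grid, sigma)
    mass = k.sum(axis=1)
    total_w = sum(p.sample_size for p in points)
    reliable = mass / total_w > mass_floor

    values = np.empty(mass.shape)
    ok = mass > 0
    values[ok] = (k[ok] @ f) / mass[ok]
    if np.any(~ok):
        lons, lats = grid.lattice()
        glon, glat = np.meshgrid(lons, lats)
        cells = np.column_stack([glon.ravel(), glat.ravel()])
        pts = np.array([[p.longitude, p.latitude] for p in points])
        for idx in np.nonzero(~ok)[0]:
            nearest = int(np.argmin(((cells[idx] - pts) ** 2).sum(axis=1)))
            values[idx] = f[nearest]
    shape = (grid.n_lat, grid.n_lon)
    return LPSurface(
        grid=grid,
        values=values.reshape(shape),
        reliable=reliable.reshape(shape),
        sigma=sigma,
        mass_floor=mass_floor,
        points=list(points),
    )


#: Geometric bandwidth ladder (degrees) searched by lowest_safe_bandwidth.
SIGMA_LADDER: tuple[float, ...] = tuple(0.25 * 2 ** (i / 2) for i in range(21))


def lowest_safe_bandwidth(
    points: Sequence[LPPoint],
    grid: GridSpec,
    mass_floor: float = 1e-6,
    ladder: Sequence[float] = SIGMA_LADDER,
) -> float:
    """Smallest sigma on the ladder for which every grid cell's relative
    kernel mass exceeds ``mass_floor`` (the 'lowest non-overflowing'
    bandwidth given the data's spatial heterogeneity)."""
    if not points:
        raise ValueError("need at least one point")
    total_w = sum(p.sample_size for p in points)
    for sigma in ladder:
        k, _ = _kernel_weights(points, grid, sigma)
        if (k.sum(axis=1) / total_w > mass_floor).all():
            return float(sigma)
    raise ValueError(
        "no bandwidth on the ladder satisfies the kernel-mass floor; "
        "use a coarser grid or a lower floor"
    )


def read_lp_table(path) -> list[LPPoint]:
    """Read a TSV of LP observations.

    Requires columns lat, lon, sample_size and either a combined
    ``allele_freq`` column or per-allele frequency columns (any column
    starting with ``freq_``), which are summed (the variants are treated as
    allelic; the sum is clipped at 1)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if "allele_freq" in df.columns:
        p = df["allele_freq"].astype(float)
    else:
        freq_cols = [c for c in df.columns if c.startswith("freq_")]
        if not freq_cols:
            raise ValueError("need an allele_freq column or freq_* columns")
        p = df[freq_cols].astype(float).sum(axis=1).clip(upper=1.0)
    return [
        LPPoint(
            latitude=float(r.lat),
            longitude=float(r.lon),
            allele_freq=float(pv),
            sample_size=int(r.sample_size),
        )
        for r, pv in zip(df.itertuples(), p)
    ]


def surface_table(surface: LPSurface):
    import pandas as pd

    lons, lats = surface.grid.lattice()
    glon, glat = np.meshgrid(lons, lats)
    return pd.DataFrame(
        {
            "lon": glon.ravel(),
            "lat": glat.ravel(),
            "phenotype_freq": surface.values.ravel(),
            "reliable": surface.reliable.ravel(),
        }
    )


def plot_surface(surface: LPSurface, path) -> None:
    """Filled-contour rendering of the smoothed phenotype frequency."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lons, lats = surface.grid.lattice()
    fig, ax = plt.subplots(figsize=(8, 6))
    cs = ax.contourf(lons, lats, surface.values, levels=10, cmap="YlOrRd")
    fig.colorbar(cs, ax=ax, label="LP phenotype frequency")
    if surface.points:
        ax.scatter(
            [p.longitude for p in surface.points],
            [p.latitude for p in surface.points],
            s=8, c="k", label="observations",
        )
        ax.legend(loc="lower left")
    ax.set_xlabel("longitude (deg)")
    ax.set_ylabel("latitude (deg)")
    ax.set_title(f"LP phenotype frequency (sigma={surface.sigma:.2f} deg)")
    fig.savefig(path, dpi=120)
    plt.close(fig)
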