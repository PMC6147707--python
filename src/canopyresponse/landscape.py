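"""Multi-scale canopy cover on a 1-km plot lattice.

Survey plots sit on the intersections of a regular 1-km grid, each carrying a
locally measured canopy-cover percentage.  Landscape-scale cover for a plot is
the unweighted mean of the cover of all existing plots whose lattice nodes fall
inside a closed disc centred on the focal plot (the focal plot included).  On a
1-km lattice the discs of radius 1.6, 3.2 and 6.4 km can hold at most 9, 37 and
129 nodes respectively; intersections that carry no plot (e.g. unforested
nodes) are simply skipped and the number of plots actually averaged is
reported.

Plots close to the domain border see truncated neighbourhoods on the outside
of the study area; :func:`exclude_border` drops every plot closer than a
margin (default 6.4 km, the largest radius) to the bounding rectangle.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_RADII: tuple[float, ...] = (1.6, 3.2, 6.4)
DEFAULT_BORDER_MARGIN: float = 6.4

#: columns every plot table must carry, in this order, before species counts
PLOT_META_COLUMNS: tuple[str, ...] = ("plot_id", "x_km", "y_km", "cover_pct")


def scale_tag(radius_km: float | str) -> str:
    """Column-name tag for a scale: ``'local'`` or e.g. ``1.6 -> '1p6'``."""
    if radius_km == "local":
        return "local"
    return format(float(radius_km), "g").replace(".", "p")


def lattice_offsets(radius_km: float, spacing_km: float = 1.0) -> list[tuple[float, float]]:
    """All lattice offsets within a closed disc of ``radius_km``.

    Returns the offsets ``(i*spacing, j*spacing)`` with Euclidean norm
    ``<= radius_km``, including ``(0, 0)``, in row-major order (increasing x,
    then increasing y).  On a 1-km lattice the radii 1.6, 3.2 and 6.4 km give
    9, 37 and 129 offsets.
    """
    if radius_km <= 0:
        raise ValueError(f"radius_km must be positive, got {radius_km}")
    if spacing_km <= 0:
        raise ValueError(f"spacing_km must be positive, got {spacing_km}")
    k = int(np.floor(radius_km / spacing_km))
    r2 = radius_km * radius_km
    out: list[tuple[float, float]] = []
    for i in range(-k, k + 1):
        xi = i * spacing_km
        for j in range(-k, k + 1):
            yj = j * spacing_km
            if xi * xi + yj * yj <= r2:
                out.append((xi, yj))
    return out


def _validate_plots(plots: pd.DataFrame) -> None:
    missing = [c for c in PLOT_META_COLUMNS if c not in plots.columns]
    if missing:
        raise ValueError(f"plot table is missing columns {missing}")
    if len(plots) == 0:
        raise ValueError("plot table is empty")
    if plots["plot_id"].duplicated().any():
        raise ValueError("duplicate plot_id in plot table")
    if plots.duplicated(subset=["x_km", "y_km"]).any():
        raise ValueError("duplicate (x_km, y_km) lattice coordinates")
    cov = plots["cover_pct"].to_numpy(float)
    if np.any(cov < 0) or np.any(cov > 100):
        raise ValueError("cover_pct outside [0, 100]")


def species_columns(plots: pd.DataFrame) -> list[str]:
    """Per-species count columns = everything beyond the meta columns."""
    return [c for c in plots.columns if c not in PLOT_META_COLUMNS]


def landscape_cover(
    plots: pd.DataFrame, radius_km: float, spacing_km: float = 1.0
) -> pd.DataFrame:
    """Mean cover over available lattice neighbours within ``radius_km``.

    Returns a frame aligned with ``plots`` holding ``plot_id``, the averaged
    cover and ``n_available``, the number of plots the mean was taken over
    (missing lattice nodes are skipped; the focal plot always counts).
    """
    _validate_plots(plots)
    offsets = lattice_offsets(radius_km, spacing_km)

    x = np.rint(plots["x_km"].to_numpy(float) / spacing_km).astype(np.int64)
    y = np.rint(plots["y_km"].to_numpy(float) / spacing_km).astype(np.int64)
    ix = x - x.min()
    iy = y - y.min()
    nx = int(ix.max()) + 1
    ny = int(iy.max()) + 1

    k = int(np.floor(radius_km / spacing_km))
    # pad by k so every shifted slice stays in bounds
    val = np.zeros((nx + 2 * k, ny + 2 * k))
    occ = np.zeros_like(val)
    val[ix + k, iy + k] = plots["cover_pct"].to_numpy(float)
    occ[ix + k, iy + k] = 1.0

    tot = np.zeros((nx, ny))
    cnt = np.zeros((nx, ny))
    for ox, oy in offsets:
        di = int(round(ox / spacing_km))
        dj = int(round(oy / spacing_km))
        sl = (slice(k + di, k + di + nx), slice(k + dj, k + dj + ny))
        tot += val[sl]
        cnt += occ[sl]

    mean = tot[ix, iy] / cnt[ix, iy]
    return pd.DataFrame(
        {
            "plot_id": plots["plot_id"].to_numpy(),
            "cover": mean,
            "n_available": cnt[ix, iy].astype(int),
        }
    )


def multiscale_cover(
    plots: pd.DataFrame,
    radii: Sequence[float] = DEFAULT_RADII,
    spacing_km: float = 1.0,
) -> pd.DataFrame:
    """Cover table with the local scale plus one column per landscape radius.

    Columns: ``plot_id, cover_local, cover_<r>, ..., n_<r>, ...`` with radius
    tags such as ``1p6``.  Local cover is the plot's own ``cover_pct``.
    """
    _validate_plots(plots)
    out = pd.DataFrame(
        {
            "plot_id": plots["plot_id"].to_numpy(),
            "cover_local": plots["cover_pct"].to_numpy(float),
        }
    )
    for r in radii:
        tag = scale_tag(r)
        lc = landscape_cover(plots, r, spacing_km)
        out[f"cover_{tag}"] = lc["cover"].to_numpy()
        out[f"n_{tag}"] = lc["n_available"].to_numpy()
    return out


def exclude_border(
    plots: pd.DataFrame,
    margin_km: float = DEFAULT_BORDER_MARGIN,
    bounds: tuple[float, float, float, float] | None = None,
) -> pd.DataFrame:
    """Drop plots closer than ``margin_km`` to the domain border.

    ``bounds`` is ``(xmin, xmax, ymin, ymax)``; by default the axis-aligned
    bounding rectangle of the plot coordinates.  A margin of 0 is the
    identity.  Raises if no plot survives, reporting the exclusion count.
    """
    _validate_plots(plots)
    if margin_km < 0:
        raise ValueError("margin_km must be >= 0")
    x = plots["x_km"].to_numpy(float)
    y = plots["y_km"].to_numpy(float)
    if bounds is None:
        bounds = (x.min(), x.max(), y.min(), y.max())
    xmin, xmax, ymin, ymax = bounds
    keep = (
        (x - xmin >= margin_km)
        & (xmax - x >= margin_km)
        & (y - ymin >= margin_km)
        & (ymax - y >= margin_km)
    )
    if not keep.any():
        raise ValueError(
            f"border exclusion with margin {margin_km} km removed all "
            f"{len(plots)} plots (domain {xmax - xmin:g} x {ymax - ymin:g} km)"
        )
    return plots.loc[keep].reset_index(drop=True)
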