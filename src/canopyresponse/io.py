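"""CSV / Newick readers and writers for the pipeline's table dialects.

Plots CSV: ``plot_id, x_km, y_km, cover_pct`` then one integer column per
species.  Cover CSV: ``plot_id, cover_local, cover_<tag>..., n_<tag>...``.
Omega CSV, fits CSV and signal CSV are flat one-row-per-record tables.
Clades CSV is two columns, ``species, clade``.  Trees travel as Newick with
branch lengths in Myr.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .landscape import PLOT_META_COLUMNS
from .occurrence import OmegaEstimate, SpeciesFit
from .phylosignal import Phylogeny

FITS_COLUMNS = ["species", "scale", "M", "C", "link", "loglik", "n_plots",
                "aicc", "aicc_intercept", "delta_aicc", "informative"]
OMEGA_COLUMNS = ["species", "scale", "omega", "ci_low", "ci_high", "n_boot",
                 "response_class", "f_low", "f_high"]


def read_plots(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PLOT_META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing plot columns {missing}")
    return df


def write_plots(plots: pd.DataFrame, path: str | Path) -> None:
    plots.to_csv(path, index=False)


def read_cover(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "plot_id" not in df.columns or "cover_local" not in df.columns:
        raise ValueError(f"{path}: not a cover table")
    return df


def write_cover(cover: pd.DataFrame, path: str | Path) -> None:
    cover.to_csv(path, index=False)


def fits_frame(fits: Iterable[SpeciesFit]) -> pd.DataFrame:
    rows = []
    for f in fits:
        d = asdict(f)
        d.pop("cov", None)
        rows.append(d)
    return pd.DataFrame(rows, columns=FITS_COLUMNS)


def omega_frame(estimates: Iterable[OmegaEstimate]) -> pd.DataFrame:
    return pd.DataFrame([asdict(e) for e in estimates], columns=OMEGA_COLUMNS)


def read_omega(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"species", "ci_low", "ci_high"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: omega table needs columns {sorted(need)}")
    return df


def read_clades(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path)
    if not {"species", "clade"}.issubset(df.columns):
        raise ValueError(f"{path}: clade table needs species, clade columns")
    return dict(zip(df["species"].astype(str), df["clade"].astype(str)))


def write_clades(clades: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"species": list(clades), "clade": [clades[s] for s in clades]}
    ).to_csv(path, index=False)


def read_tree(path: str | Path, clades: dict[str, str] | None = None) -> Phylogeny:
    return Phylogeny.from_newick(str(path), clades=clades)


def write_tree(phylo: Phylogeny, path: str | Path) -> None:
    phylo.write_newick(str(path))
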