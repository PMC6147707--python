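"""End-to-end orchestration: simulate -> landscape -> fit -> phylogenetic signal.

``run_pipeline`` composes the stages with a single master seed, emits the
cover, fits, omega and signal tables plus a JSON-able run manifest (per-stage
counts: plots excluded at the border, species retained, informative fits per
scale), and ``summarize`` condenses the omega table into per-scale response
fractions and per-species best scales.  The defaults reproduce the standard
settings of the analysis: landscape radii 1.6/3.2/6.4 km, border margin
6.4 km, occurrence probabilities compared at 5% vs 75% cover, species kept
from 25 occupied plots, 1000 bootstrap replicates and 1000 signal iterations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as crio
from . import __version__
from .landscape import (DEFAULT_BORDER_MARGIN, DEFAULT_RADII, exclude_border,
                        multiscale_cover, scale_tag)
from .occurrence import (DEFAULT_F_HIGH, DEFAULT_F_LOW, DEFAULT_MIN_OCCUPIED,
                         DEFAULT_N_BOOT, OmegaEstimate, SpeciesFit, best_scale,
                         bootstrap_omega, fit_poisson, select_species,
                         species_seed)
from .phylosignal import DEFAULT_N_ITER, LambdaResult, Phylogeny, clade_subset_signal
from .synthetic import SyntheticConfig, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; defaults are the standard settings."""

    radii: Sequence[float] = DEFAULT_RADII
    border_margin: float = DEFAULT_BORDER_MARGIN
    f_low: float = DEFAULT_F_LOW
    f_high: float = DEFAULT_F_HIGH
    min_occupied: int = DEFAULT_MIN_OCCUPIED
    n_boot: int = DEFAULT_N_BOOT
    n_iter: int = DEFAULT_N_ITER
    link: str = "identity"
    occupied_only: bool = False  # fit on occupied plots only (alternate reading)
    seed: int = 0
    # inputs: either paths ...
    plots_csv: str | None = None
    tree_newick: str | None = None
    clades_csv: str | None = None
    # ... or a synthetic generator config
    synthetic: SyntheticConfig | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        r = list(self.radii)
        if any(x <= 0 for x in r) or sorted(r) != r:
            raise ValueError("radii must be positive and ascending")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn is not None:
            cfg.synthetic = SyntheticConfig(**syn)
        return cfg


@dataclass
class PipelineResult:
    plots: pd.DataFrame
    cover: pd.DataFrame
    fits: pd.DataFrame
    omegas: pd.DataFrame
    best_scales: pd.DataFrame
    signal: pd.DataFrame
    signal_iterations: pd.DataFrame
    manifest: dict
    tree: Phylogeny
    truth: object | None = None
    fit_objects: dict = field(default_factory=dict, repr=False)


def _scales(radii: Sequence[float]) -> list[str]:
    return ["local"] + [scale_tag(r) for r in radii]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and return the bundled tables plus the manifest."""
    # --- inputs -----------------------------------------------------------
    truth = None
    if config.synthetic is not None:
        syn = config.synthetic
        plots, tree, truth = simulate_dataset(syn)
        clades = tree.clades
    elif config.plots_csv and config.tree_newick:
        plots = crio.read_plots(config.plots_csv)
        clades = crio.read_clades(config.clades_csv) if config.clades_csv else {}
        tree = crio.read_tree(config.tree_newick, clades=clades)
    else:
        raise ValueError("config needs either `synthetic` or plots_csv + tree_newick")

    n_raw = len(plots)

    # --- landscape --------------------------------------------------------
    try:
        if config.border_margin > 0:
            plots = exclude_border(plots, config.border_margin)
        cover = multiscale_cover(plots, config.radii)
    except ValueError as exc:
        raise RuntimeError(f"stage landscape: {exc}") from exc
    n_retained = len(plots)

    # --- species selection and occurrence fits ----------------------------
    scales = _scales(config.radii)
    try:
        species = select_species(plots, tree.tip_labels, config.min_occupied)
    except ValueError as exc:
        raise RuntimeError(f"stage select_species: {exc}") from exc

    fit_objs: dict[tuple[str, str], SpeciesFit] = {}
    omega_list: list[OmegaEstimate] = []
    for sp in species:
        counts = plots[sp].to_numpy()
        for si, sc in enumerate(scales):
            F_all = cover[f"cover_{sc}" if sc != "local" else "cover_local"].to_numpy()
            mask = counts > 0 if config.occupied_only else np.ones(len(counts), bool)
            y, F = counts[mask], F_all[mask]
            try:
                fit = fit_poisson(y, F, config.link, species=sp, scale=sc)
            except ValueError as exc:
                raise RuntimeError(f"stage fit [{sp}/{sc}]: {exc}") from exc
            fit_objs[(sp, sc)] = fit
            if fit.informative:
                try:
                    est = bootstrap_omega(
                        y, F, config.link, n_boot=config.n_boot,
                        seed=species_seed(config.seed, sp) + [si],
                        f_low=config.f_low, f_high=config.f_high,
                        species=sp, scale=sc,
                    )
                except RuntimeError as exc:
                    # degenerate bootstrap: species kept in the fits table but
                    # reported without Omega, like other unexplained species
                    logger.warning("bootstrap failed, species dropped from "
                                   "Omega table: %s", exc)
                    continue
                omega_list.append(est)
            else:
                logger.info("species %s at scale %s: cover model uninformative "
                            "(delta AICc %.2f)", sp, sc, fit.delta_aicc)

    fits_df = crio.fits_frame(fit_objs.values())
    omega_df = crio.omega_frame(omega_list)
    best_df = pd.DataFrame(
        {
            "species": species,
            "best_scale": [
                best_scale([fit_objs[(sp, sc)] for sc in scales]) for sp in species
            ],
        }
    )

    # --- phylogenetic signal per scale and clade scope --------------------
    sig_rows, iter_rows = [], []
    for sc in scales:
        sub = omega_df[omega_df["scale"] == sc]
        if len(sub) < 3:
            logger.info("scale %s: fewer than 3 species with Omega; signal skipped", sc)
            continue
        scopes = clade_subset_signal(sub, tree, clades, n_iter=config.n_iter,
                                     seed=config.seed)
        for scope, res in scopes.items():
            if res is None:
                sig_rows.append({"scale": sc, "scope": scope, "n_tips": 0,
                                 "n_iter": config.n_iter, "median_lambda": np.nan,
                                 "median_p": np.nan, "lambda_point": np.nan,
                                 "p_point": np.nan})
                continue
            sig_rows.append({"scale": sc, "scope": scope, "n_tips": res.n_tips,
                             "n_iter": res.n_iter,
                             "median_lambda": res.median_lambda,
                             "median_p": res.median_p,
                             "lambda_point": res.lambda_hat,
                             "p_point": res.p_value})
            it = res.iterations.copy()
            it.insert(0, "scope", scope)
            it.insert(0, "scale", sc)
            iter_rows.append(it)
    signal_df = pd.DataFrame(sig_rows)
    iters_df = (pd.concat(iter_rows, ignore_index=True)
                if iter_rows else pd.DataFrame())

    # --- manifest ---------------------------------------------------------
    n_informative = {sc: int((fits_df.loc[fits_df["scale"] == sc, "informative"]).sum())
                     for sc in scales}
    cfg_dict = asdict(config)
    manifest = {
        "version": __version__,
        "config": cfg_dict,
        "seed": config.seed,
        "n_plots_input": n_raw,
        "n_plots_border_excluded": n_raw - n_retained,
        "n_plots_retained": n_retained,
        "n_species_retained": len(species),
        "n_informative_by_scale": n_informative,
        "scales": scales,
    }

    result = PipelineResult(
        plots=plots, cover=cover, fits=fits_df, omegas=omega_df,
        best_scales=best_df, signal=signal_df, signal_iterations=iters_df,
        manifest=manifest, tree=tree, truth=truth, fit_objects=fit_objs,
    )
    if config.out_dir:
        write_results(result, config.out_dir)
    return result


def write_results(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    crio.write_plots(result.plots, out / "plots.csv")
    crio.write_cover(result.cover, out / "cover.csv")
    result.fits.to_csv(out / "fits.csv", index=False)
    result.omegas.to_csv(out / "omega.csv", index=False)
    result.best_scales.to_csv(out / "best_scales.csv", index=False)
    result.signal.to_csv(out / "signal.csv", index=False)
    if len(result.signal_iterations):
        result.signal_iterations.to_csv(out / "signal_iterations.csv", index=False)
    crio.write_tree(result.tree, out / "tree.nwk")
    if result.tree.clades:
        crio.write_clades(result.tree.clades, out / "clades.csv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)


def summarize(result: PipelineResult) -> tuple[pd.DataFrame, str]:
    """Per-scale response-class counts/fractions and best-scale fractions.

    At each scale the negative/neutral/positive/unexplained counts partition
    the retained species; 'unexplained' species are those whose cover model
    was not informative at that scale (the gaps of the response figure).
    """
    species = list(result.best_scales["species"])
    n_sp = len(species)
    scales = result.manifest["scales"]
    rows = []
    for sc in scales:
        sub = result.omegas[result.omegas["scale"] == sc]
        counts = {"negative": 0, "neutral": 0, "positive": 0}
        counts.update(sub["response_class"].value_counts().to_dict())
        unexplained = n_sp - len(sub)
        row = {"scale": sc, "n_species": n_sp, "unexplained": unexplained}
        for cls in ("negative", "neutral", "positive"):
            row[cls] = counts[cls]
            row[f"frac_{cls}"] = counts[cls] / n_sp if n_sp else np.nan
        row["frac_informative"] = len(sub) / n_sp if n_sp else np.nan
        rows.append(row)
    table = pd.DataFrame(rows)

    best = result.best_scales["best_scale"]
    lines = []
    for _, r in table.iterrows():
        lines.append(
            f"scale {r['scale']}: {int(r['negative'])} negative "
            f"({r['frac_negative']:.0%}), {int(r['neutral'])} neutral "
            f"({r['frac_neutral']:.0%}), {int(r['positive'])} positive "
            f"({r['frac_positive']:.0%}), {int(r['unexplained'])} unexplained"
        )
    explained = best.notna().sum()
    for sc in scales:
        n_best = int((best == sc).sum())
        frac = n_best / explained if explained else float("nan")
        lines.append(f"best scale {sc}: {n_best}/{explained} species ({frac:.0%})")
    return table, "\n".join(lines)
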