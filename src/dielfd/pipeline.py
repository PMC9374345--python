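"""High-level orchestration of the analysis stages.

These functions are the library-level implementation behind the CLI
subcommands: they resolve a :class:`~dielfd.config.RunConfig`, load or
simulate inputs, and return plain DataFrames ready to be written as CSV.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from . import biogeo, core, dendro, spectrum, synth, traits
from .config import RunConfig

log = logging.getLogger("dielfd")

__all__ = [
    "load_inputs",
    "run_riskstats",
    "run_spectra",
    "run_fdmaps",
    "run_congruence",
]


def load_inputs(config: RunConfig) -> tuple[core.SpeciesTable, biogeo.PresenceAbsence]:
    """Load the species table and presence-absence grid, simulating when absent."""
    params = _synth_params(config)
    if config.species_table is not None:
        table = core.read_species_table(config.species_table)
    else:
        table, _ = synth.generate_species(params, config.seed)
    if config.presence_absence is not None:
        pa = biogeo.PresenceAbsence.from_sparse_csv(
            config.presence_absence, species_ids=table.species_ids
        )
    else:
        pa = synth.generate_ranges(table, params, config.seed)
    return table, pa


def _synth_params(config: RunConfig) -> synth.GeneratorParams:
    over = {} if config.n_species is None else {"n_species": config.n_species}
    if config.synth_preset == "global_mammals" and config.n_species is None:
        return synth.GeneratorParams.global_mammals()
    if config.synth_preset == "global_mammals":
        # scaled-down global_mammals keeps the niche shares and threat rates
        return synth.GeneratorParams(
            niche_threat_rates=(0.316, 0.348, 0.349, 0.413),
            exact_threat_counts=True,
            beta_mass=1.0,
            beta_breadth=-0.5,
            **over,
        )
    return synth.GeneratorParams(**over)


def run_riskstats(config: RunConfig, table: core.SpeciesTable | None = None) -> pd.DataFrame:
    """Per-niche removal counts, proportions, and log-odds contrasts per scenario."""
    if table is None:
        table, _ = load_inputs(config)
    frames = []
    for name in config.scenarios:
        summ = core.niche_threat_summary(table, name)
        t = summ.table.copy()
        t.insert(0, "scenario", name)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def run_spectra(
    config: RunConfig, table: core.SpeciesTable | None = None
) -> tuple[pd.DataFrame, dict]:
    """Spectrum change statistics with null intervals per (niche, scenario).

    Returns the statistics table and a dict of per-(niche, scenario) grids
    (full KDE, survivor KDE, change result) for optional serialization.
    Niches with fewer than 10 species are skipped with a warning; a scenario
    removing no species in a niche yields a zero-change row.
    """
    if table is None:
        table, _ = load_inputs(config)
    tt = traits.transform_traits(table)
    rows = []
    grids: dict[tuple[str, str], dict] = {}
    for niche in config.niches:
        sub = table.niche_subset(niche)
        if len(sub) < 10:
            warnings.warn(f"niche {niche!r} has < 10 species; skipped")
            continue
        basis = spectrum.fit_pca(tt, sub.species_ids)
        scores = basis.scores.to_numpy()
        grid = spectrum.GridSpec.from_scores(
            scores, expand=config.grid_expand, n=config.grid_size
        )
        for name in config.scenarios:
            scen = core.SCENARIOS[name]
            removed = scen.removal_mask(sub)
            if removed.sum() == 0:
                rows.append(
                    {
                        "niche": niche,
                        "scenario": name,
                        "n": len(sub),
                        "n_removed": 0,
                        "mean_abs_density_change": 0.0,
                        "volume_loss": 0.0,
                        "null_lo_change": 0.0,
                        "null_hi_change": 0.0,
                        "null_lo_volume": 0.0,
                        "null_hi_volume": 0.0,
                    }
                )
                continue
            res = spectrum.spectrum_null(
                scores,
                removed,
                reps=config.reps,
                seed=_combine_seed(config.seed, niche, name),
                bandwidth=config.bandwidth,
                grid=grid,
            )
            ch, vol = res["mean_abs_density_change"], res["volume_loss"]
            rows.append(
                {
                    "niche": niche,
                    "scenario": name,
                    "n": len(sub),
                    "n_removed": int(removed.sum()),
                    "mean_abs_density_change": ch.observed,
                    "volume_loss": vol.observed,
                    "null_lo_change": ch.interval[0],
                    "null_hi_change": ch.interval[1],
                    "null_lo_volume": vol.interval[0],
                    "null_hi_volume": vol.interval[1],
                }
            )
            grids[(niche, name)] = {
                "basis": basis,
                "null": res,
                "grid": grid,
                "change": res["observed_change"],
            }
    return pd.DataFrame(rows), grids


def _combine_seed(seed: int, *parts: str) -> int:
    h = 0
    for p in parts:
        for ch in str(p):
            h = (h * 31 + ord(ch)) % 100003
    return (seed * 100003 + h) % (2**31 - 1)


def run_fdmaps(
    config: RunConfig,
    table: core.SpeciesTable | None = None,
    pa: biogeo.PresenceAbsence | None = None,
    with_null: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FD maps with proportional loss (and null comparison) per niche/scenario.

    Returns (per-pixel map table, UIQ summary table).  A niche whose pixels
    are all excluded yields an empty map with a warning, not a failure.
    """
    if table is None or pa is None:
        table, pa = load_inputs(config)
    tt = traits.transform_traits(table)
    gower = dendro.gower_matrix(tt)
    tree = dendro.upgma(gower)
    coph = dendro.cophenetic_matrix(tree)

    maps, summaries = [], []
    for niche in config.niches:
        for name in config.scenarios:
            if with_null:
                m = biogeo.pixel_null(
                    pa,
                    coph,
                    table,
                    niche,
                    name,
                    reps=config.reps,
                    seed=_combine_seed(config.seed, "fdmap", niche, name),
                    exclude_threshold=config.exclude_threshold,
                )
            else:
                m = biogeo.proportion_fd_lost(
                    pa, coph, table, niche, name, config.exclude_threshold
                )
            maps.append(m)
            inc = m.loc[m["included"] & m["prop_lost"].notna()]
            if inc.empty:
                warnings.warn(
                    f"all pixels excluded for niche {niche!r}; empty map"
                )
                continue
            summaries.append(
                {
                    "niche": niche,
                    "scenario": name,
                    "n_pixels": int(len(inc)),
                    "uiq_prop_lost": biogeo.uiq(inc["prop_lost"]),
                    "median_prop_lost": float(inc["prop_lost"].median()),
                    "mean_obs_minus_null": (
                        float(inc["obs_minus_null"].mean()) if with_null else np.nan
                    ),
                }
            )
    return pd.concat(maps, ignore_index=True), pd.DataFrame(summaries)


def run_congruence(config: RunConfig, table: core.SpeciesTable | None = None) -> dict:
    """Gower-vs-cophenetic congruence of the global functional dendrogram."""
    if table is None:
        table, _ = load_inputs(config)
    tt = traits.transform_traits(table)
    gower = dendro.gower_matrix(tt)
    tree = dendro.upgma(gower)
    return dendro.congruence(gower, tree)

def change_grid_frame(grid, change) -> "pd.DataFrame":
    """Flatten a ChangeResult to the gridded CSV dialect."""
    pts = grid.points()
    ix, iy = np.meshgrid(np.arange(grid.nx), np.arange(grid.ny), indexing="ij")
    return pd.DataFrame(
        {
            "x_index": ix.ravel(),
            "y_index": iy.ravel(),
            "x": pts[:, 0],
            "y": pts[:, 1],
            "delta": change.delta.ravel(),
            "boundary_lost": change.boundary_loss_mask.ravel(),
        }
    )
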