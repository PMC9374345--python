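"""Synthetic species tables and range grids with the structure the analysis assumes.

The generator emulates a global terrestrial-mammal dataset: four diel niches
with strongly unequal shares (nocturnal ~69.5%, crepuscular ~2.2%, cathemeral
~10.5%, diurnal ~17.8%), right-skewed body masses (log-normal, niche-specific
location), log-normal litter sizes, habitat breadths as 1 + Poisson counts,
niche-specific foraging-stratum frequencies (bats make "aerial" common only
among nocturnal/crepuscular species), and Dirichlet diet-category profiles
drawn from a small set of guilds (invertivore, carnivore, frugivore/
herbivore, omnivore).

Threat status follows a logistic model on the standardized transformed
traits: logit p = logit(baseline) + beta . z.  Positive beta on body mass
makes heavier species likelier to be threatened, clustering threatened
species in trait space — the property the spectrum and pixel null models are
designed to detect.  Threatened species are split across CR/EN/VU/NT/
threatened-DD; a small share of the non-threatened pool is relabeled DD
(non-threatened) to exercise the conservative DD handling.

Ranges are contiguous disc-like pixel blocks with log-normal sizes; range
centers are biased along the grid's row axis to impose a latitudinal richness
gradient.

The ``global_mammals`` preset pins the niche counts to (3498, 113, 526, 896) and
the per-niche NT-scenario threat rates to (0.316, 0.348, 0.349, 0.413),
drawing exactly the corresponding number of threatened species per niche
(weighted by the logistic model when betas are nonzero) so end-to-end runs
reproduce those marginal rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biogeo import PresenceAbsence
from .core import DIET_CATEGORY_COLUMNS, NICHES, SpeciesTable
from .traits import ordinate_diet, transform_traits

__all__ = ["GeneratorParams", "generate_species", "generate_ranges", "generate_dataset"]

#: how threatened species are split across statuses (CR, EN, VU, NT, DD-threatened)
DEFAULT_STATUS_SPLIT = (0.15, 0.25, 0.30, 0.22, 0.08)


@dataclass
class GeneratorParams:
    """Knobs of the synthetic world; defaults encode the study conditions."""

    n_species: int = 1000
    niche_proportions: tuple[float, float, float, float] = (0.695, 0.022, 0.105, 0.178)
    exact_niche_counts: tuple[int, int, int, int] | None = None

    # traits: log10 body-mass location/scale per niche (grams); mammal-like
    # (nocturnal dominated by small rodents and bats, cathemeral includes
    # megafauna)
    mass_log10_mean: tuple[float, float, float, float] = (1.6, 2.6, 2.8, 2.4)
    mass_log10_sd: tuple[float, float, float, float] = (0.8, 1.0, 1.2, 1.0)
    litter_log_mean: float = 0.8
    litter_log_sd: float = 0.5
    #: fast-slow life-history axis: litter size declines with body mass
    #: (log litter per log10 gram)
    litter_mass_slope: float = -0.45
    habitat_breadth_rate: float = 3.0  # breadth = 1 + Poisson(rate)
    #: foraging stratum probabilities (ground, scansorial, arboreal, aerial)
    stratum_probs: tuple[tuple[float, ...], ...] = (
        (0.45, 0.15, 0.20, 0.20),  # nocturnal (bats)
        (0.55, 0.15, 0.15, 0.15),  # crepuscular
        (0.75, 0.15, 0.10, 0.00),  # cathemeral
        (0.55, 0.20, 0.25, 0.00),  # diurnal
    )
    diet_dirichlet_concentration: float = 0.6

    # threat model
    baseline_threat_rate: float = 0.33
    niche_threat_rates: tuple[float, float, float, float] | None = None
    beta_mass: float = 0.0
    beta_litter: float = 0.0
    beta_breadth: float = 0.0
    beta_stratum: float = 0.0
    beta_diet: float = 0.0
    exact_threat_counts: bool = False
    status_split: tuple[float, ...] = DEFAULT_STATUS_SPLIT
    dd_nonthreatened_rate: float = 0.03

    # geography
    grid_rows: int = 20
    grid_cols: int = 20
    range_log_mean: float = 3.0  # log pixel count
    range_log_sd: float = 1.0
    richness_gradient: float = 1.0  # >0: richer toward high row index

    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.niche_proportions, dtype=float)
        if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
            raise ValueError("niche proportions must be non-negative and sum to 1")
        s = np.asarray(self.status_split, dtype=float)
        if abs(s.sum() - 1.0) > 1e-9 or (s < 0).any():
            raise ValueError("status split must be a probability vector")
        if not 0.0 <= self.baseline_threat_rate < 1.0:
            raise ValueError("baseline threat rate must be in [0, 1)")

    @classmethod
    def global_mammals(cls, **overrides) -> "GeneratorParams":
        """Preset matching the printed niche counts and NT-scenario rates."""
        base = dict(
            n_species=5033,
            exact_niche_counts=(3498, 113, 526, 896),
            niche_threat_rates=(0.316, 0.348, 0.349, 0.413),
            exact_threat_counts=True,
            beta_mass=1.0,
            beta_breadth=-0.5,
        )
        base.update(overrides)
        return cls(**base)

    def betas(self) -> np.ndarray:
        return np.array(
            [
                self.beta_mass,
                self.beta_litter,
                self.beta_breadth,
                self.beta_stratum,
                self.beta_diet,
            ]
        )


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


#: guild archetypes as Dirichlet mean weights over the 10 diet categories
_GUILDS = np.array(
    [
        # inv  vend  vect  fish  vunk  scav  fruit nect  seed  plant
        [0.70, 0.05, 0.05, 0.02, 0.03, 0.05, 0.05, 0.01, 0.02, 0.02],  # invertivore
        [0.10, 0.35, 0.15, 0.10, 0.10, 0.10, 0.05, 0.00, 0.00, 0.05],  # carnivore
        [0.02, 0.00, 0.00, 0.00, 0.00, 0.00, 0.35, 0.08, 0.20, 0.35],  # herb/frugivore
        [0.20, 0.08, 0.05, 0.02, 0.05, 0.05, 0.20, 0.05, 0.15, 0.15],  # omnivore
    ]
)
_GUILD_PROBS_BY_NICHE = np.array(
    [
        [0.45, 0.10, 0.25, 0.20],  # nocturnal: many invertivores (bats, rodents)
        [0.25, 0.15, 0.35, 0.25],  # crepuscular
        [0.10, 0.20, 0.45, 0.25],  # cathemeral: grazers, carnivores
        [0.20, 0.10, 0.40, 0.30],  # diurnal
    ]
)


def generate_species(
    params: GeneratorParams, seed: int | None = None
) -> tuple[SpeciesTable, pd.DataFrame]:
    """Draw a complete synthetic species table plus its diet-category table.

    The returned table carries a ``diet_score`` column obtained by running the
    diet ordination on the generated categories, so it is directly usable by
    every downstream stage.  Separate random substreams are used for traits,
    diet, threat, and status so that adding later stages does not perturb
    earlier draws under the same master seed.
    """
    master = np.random.SeedSequence(params.seed if seed is None else seed)
    s_niche, s_traits, s_diet, s_threat, s_status = (
        np.random.default_rng(c) for c in master.spawn(5)
    )
    n = params.n_species

    if params.exact_niche_counts is not None:
        counts = np.asarray(params.exact_niche_counts, dtype=int)
        if counts.sum() != n:
            raise ValueError("exact niche counts must sum to n_species")
        niche_idx = np.repeat(np.arange(4), counts)
    else:
        niche_idx = s_niche.choice(4, size=n, p=np.asarray(params.niche_proportions))
    niches = np.asarray(NICHES)[niche_idx]

    mu = np.asarray(params.mass_log10_mean)[niche_idx]
    sd = np.asarray(params.mass_log10_sd)[niche_idx]
    log10_mass = s_traits.normal(mu, sd)
    body_mass = 10.0**log10_mass
    litter_mu = params.litter_log_mean + params.litter_mass_slope * (
        log10_mass - log10_mass.mean()
    )
    litter = np.exp(s_traits.normal(litter_mu, params.litter_log_sd))
    breadth = 1 + s_traits.poisson(params.habitat_breadth_rate, n)
    strat_probs = np.asarray(params.stratum_probs)[niche_idx]
    u = s_traits.random(n)
    stratum = 1 + (u[:, None] > strat_probs.cumsum(axis=1)).sum(axis=1)
    stratum = np.clip(stratum, 1, 4)

    guilds = np.array(
        [s_diet.choice(4, p=_GUILD_PROBS_BY_NICHE[k]) for k in niche_idx]
    )
    alpha = params.diet_dirichlet_concentration * 10.0 * _GUILDS[guilds] + 1e-3
    diet_frac = np.vstack([s_diet.dirichlet(a) for a in alpha])
    # semi-quantitative 0-100 use scores in steps of 10, at least one nonzero
    diet_cats = np.round(diet_frac * 10.0) * 10.0
    zero_rows = diet_cats.sum(axis=1) == 0
    diet_cats[zero_rows, np.argmax(diet_frac[zero_rows], axis=1)] = 10.0

    ids = np.array([f"sp{i:04d}" for i in range(n)])
    diet_table = pd.DataFrame(diet_cats, index=ids, columns=list(DIET_CATEGORY_COLUMNS))
    ordination = ordinate_diet(diet_table)

    df = pd.DataFrame(
        {
            "species_id": ids,
            "diel_niche": niches,
            "iucn_status": "LC",
            "dd_threatened": False,
            "body_mass_g": body_mass,
            "litter_size": litter,
            "habitat_breadth": breadth,
            "foraging_stratum": stratum,
            "diet_score": ordination.axis1.to_numpy(),
        }
    )
    table = SpeciesTable(df, diet_table)

    # threat assignment: logistic on standardized transformed traits
    Z = transform_traits(table).matrix()
    eta = Z @ params.betas()
    rates = (
        np.asarray(params.niche_threat_rates)[niche_idx]
        if params.niche_threat_rates is not None
        else np.full(n, params.baseline_threat_rate)
    )
    lp = np.array([_logit(r) for r in rates]) + eta
    if params.exact_threat_counts:
        threatened = np.zeros(n, dtype=bool)
        # Gumbel top-k: weighted sampling without replacement by the logistic
        # propensity, hitting the per-niche count exactly
        gumbel = s_threat.gumbel(size=n)
        for k in range(4):
            sel = niche_idx == k
            nk = int(sel.sum())
            if nk == 0:
                continue
            target = int(round(rates[sel][0] * nk))
            order = np.argsort(lp[sel] + gumbel[sel])[::-1]
            idx = np.flatnonzero(sel)[order[:target]]
            threatened[idx] = True
    else:
        threatened = s_threat.random(n) < _expit(lp)

    status = np.full(n, "LC", dtype=object)
    dd_flag = np.zeros(n, dtype=bool)
    split = np.asarray(params.status_split)
    labels = np.array(["CR", "EN", "VU", "NT", "DD"], dtype=object)
    tidx = np.flatnonzero(threatened)
    drawn = s_status.choice(5, size=len(tidx), p=split)
    status[tidx] = labels[drawn]
    dd_flag[tidx[drawn == 4]] = True
    # a slice of the non-threatened pool is DD with no threat prediction
    nt_idx = np.flatnonzero(~threatened)
    dd_extra = nt_idx[s_status.random(len(nt_idx)) < params.dd_nonthreatened_rate]
    status[dd_extra] = "DD"

    df = table.df.copy()
    df["iucn_status"] = status
    df["dd_threatened"] = dd_flag
    return SpeciesTable(df, diet_table), diet_table


def generate_ranges(
    table: SpeciesTable, params: GeneratorParams, seed: int | None = None
) -> PresenceAbsence:
    """Contiguous disc-like ranges on the abstract grid with a richness gradient.

    Each species occupies its log-normally-sized count of pixels nearest to a
    randomly placed center (ties broken by pixel index), guaranteeing
    contiguity and at least one pixel per species.  Centers are biased along
    the row axis with weight exp(gradient * row / (rows-1)).
    """
    master = np.random.SeedSequence(params.seed if seed is None else seed)
    rng = np.random.default_rng(master.spawn(7)[6])
    rows, cols = params.grid_rows, params.grid_cols
    n_pix = rows * cols
    if n_pix < 1:
        raise ValueError("empty grid")
    coords = np.array([(r, c) for r in range(rows) for c in range(cols)], dtype=float)

    row_weights = np.exp(
        params.richness_gradient * coords[:, 0] / max(rows - 1, 1)
    )
    row_weights /= row_weights.sum()

    n = len(table)
    sizes = np.exp(rng.normal(params.range_log_mean, params.range_log_sd, n))
    sizes = np.clip(np.round(sizes), 1, n_pix).astype(int)

    M = np.zeros((n_pix, n), dtype=bool)
    centers = rng.choice(n_pix, size=n, p=row_weights)
    jitter = rng.random((n, 2)) - 0.5
    for j in range(n):
        center = coords[centers[j]] + jitter[j]
        d2 = ((coords - center) ** 2).sum(axis=1)
        nearest = np.lexsort((np.arange(n_pix), d2))[: sizes[j]]
        M[nearest, j] = True

    pixel_ids = np.array([f"px{r:03d}_{c:03d}" for r in range(rows) for c in range(cols)])
    pixel_coords = pd.DataFrame(
        {"pixel_id": pixel_ids, "row": coords[:, 0].astype(int), "col": coords[:, 1].astype(int)}
    )
    return PresenceAbsence(pixel_ids, table.species_ids.copy(), M, pixel_coords)


def generate_dataset(
    params: GeneratorParams, seed: int | None = None
) -> tuple[SpeciesTable, pd.DataFrame, PresenceAbsence]:
    """Species table, diet categories, and presence-absence grid in one call."""
    table, diet = generate_species(params, seed)
    pa = generate_ranges(table, params, seed)
    return table, diet, pa
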