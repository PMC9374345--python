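"""Species table data model, CSV I/O, extinction scenarios, and threat summaries.

The universal input of the pipeline is a table with one row per species
carrying its diel niche (when in the 24-h cycle it is physically active), its
IUCN Red List status, and five functional traits: adult body mass (g), litter
size, habitat breadth (number of suitable habitats), foraging stratum
(ordinal: ground = 1, scansorial = 2, arboreal = 3, aerial = 4), and a
continuous diet score (an ordination axis over semi-quantitative diet
categories; see :mod:`dielfd.traits`).

Functional-extinction scenarios remove species by threat status in a nested,
progressive order: CR, then CR+EN, then CR+EN+VU, then CR+EN+VU+NT plus Data
Deficient species predicted threatened by trait-based classifiers.  A scenario
is named after the *lowest* threat category it removes.  DD species with no
threat prediction are conservatively treated as non-threatened and are never
removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "NICHES",
    "STATUSES",
    "SCENARIOS",
    "SCENARIO_ORDER",
    "ExtinctionScenario",
    "SpeciesTable",
    "SchemaError",
    "ValidationError",
    "read_species_table",
    "write_species_table",
    "apply_scenario",
    "niche_threat_summary",
]

NICHES: tuple[str, ...] = ("nocturnal", "crepuscular", "cathemeral", "diurnal")
STATUSES: tuple[str, ...] = ("CR", "EN", "VU", "NT", "LC", "DD")

#: Columns every species table must provide (diet may instead come as
#: ``diet_cat_1`` .. ``diet_cat_10`` semi-quantitative categories).
REQUIRED_COLUMNS = (
    "species_id",
    "diel_niche",
    "iucn_status",
    "dd_threatened",
    "body_mass_g",
    "litter_size",
    "habitat_breadth",
    "foraging_stratum",
)

DIET_CATEGORY_COLUMNS = tuple(f"diet_cat_{i}" for i in range(1, 11))

#: Diet categories 1-6 describe animal food sources (invertebrates,
#: endothermic/ectothermic vertebrates, fish, unknown vertebrates, carrion),
#: 7-10 plant sources (fruit, nectar, seeds, other plant material).  Used for
#: the sign convention of the diet ordination axis.
PLANT_DIET_CATEGORIES = ("diet_cat_7", "diet_cat_8", "diet_cat_9", "diet_cat_10")


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class ValidationError(ValueError):
    """Row-level contents violate the data model."""


@dataclass(frozen=True)
class ExtinctionScenario:
    """A nested functional-extinction scenario.

    ``removed_statuses`` lists the IUCN categories treated as functionally
    extinct; ``include_threatened_dd`` additionally removes DD species whose
    ``dd_threatened`` flag is set.
    """

    name: str
    removed_statuses: tuple[str, ...]
    include_threatened_dd: bool = False

    def removal_mask(self, table: "SpeciesTable") -> np.ndarray:
        df = table.df
        mask = df["iucn_status"].isin(self.removed_statuses).to_numpy()
        if self.include_threatened_dd:
            mask |= (
                (df["iucn_status"] == "DD") & df["dd_threatened"]
            ).to_numpy()
        return mask


SCENARIOS: dict[str, ExtinctionScenario] = {
    "CR": ExtinctionScenario("CR", ("CR",)),
    "EN": ExtinctionScenario("EN", ("CR", "EN")),
    "VU": ExtinctionScenario("VU", ("CR", "EN", "VU")),
    "NT": ExtinctionScenario(
        "NT", ("CR", "EN", "VU", "NT"), include_threatened_dd=True
    ),
}

#: Progressive order, from the most conservative to the most extreme scenario.
SCENARIO_ORDER: tuple[str, ...] = ("CR", "EN", "VU", "NT")

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def _parse_bool(values: pd.Series) -> pd.Series:
    def one(v: object) -> bool:
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        if isinstance(v, (int, np.integer, float)):
            return bool(v) and not (isinstance(v, float) and math.isnan(v))
        s = str(v).strip().lower()
        if s in _TRUE:
            return True
        if s in _FALSE or s == "nan":
            return False
        raise ValidationError(f"unparseable boolean value {v!r} in dd_threatened")

    return values.map(one).astype(bool)


class SpeciesTable:
    """Validated species × trait table.

    Wraps a :class:`pandas.DataFrame` whose rows follow the CSV dialect of the
    pipeline; an optional ``diet_categories`` frame (species × 10) carries the
    raw semi-quantitative diet records when the continuous ``diet_score`` has
    not been computed yet.
    """

    def __init__(self, df: pd.DataFrame, diet_categories: pd.DataFrame | None = None):
        self.df = df.reset_index(drop=True)
        self.diet_categories = diet_categories
        self._validate()

    # -- construction -------------------------------------------------
    def _validate(self) -> None:
        df = self.df
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        has_diet_score = "diet_score" in df.columns and df["diet_score"].notna().all()
        has_diet_cats = self.diet_categories is not None or all(
            c in df.columns for c in DIET_CATEGORY_COLUMNS
        )
        if not (has_diet_score or has_diet_cats):
            raise SchemaError(
                "need either a complete diet_score column or diet_cat_1..diet_cat_10"
            )
        if self.diet_categories is None and all(
            c in df.columns for c in DIET_CATEGORY_COLUMNS
        ):
            self.diet_categories = df.set_index("species_id")[
                list(DIET_CATEGORY_COLUMNS)
            ].astype(float)

        df["species_id"] = df["species_id"].astype(str).str.strip()
        if df["species_id"].duplicated().any():
            dups = df.loc[df["species_id"].duplicated(), "species_id"].tolist()
            raise ValidationError(f"duplicate species_id values: {dups}")

        df["diel_niche"] = df["diel_niche"].astype(str).str.strip().str.lower()
        bad = sorted(set(df["diel_niche"]) - set(NICHES))
        if bad:
            raise ValidationError(f"unknown diel_niche label(s): {bad}")

        df["iucn_status"] = df["iucn_status"].astype(str).str.strip().str.upper()
        bad = sorted(set(df["iucn_status"]) - set(STATUSES))
        if bad:
            raise ValidationError(f"unknown iucn_status code(s): {bad}")

        df["dd_threatened"] = _parse_bool(df["dd_threatened"])

        for col in ("body_mass_g", "litter_size"):
            df[col] = pd.to_numeric(df[col])
            nonpos = df.loc[~(df[col] > 0), "species_id"].tolist()
            if nonpos:
                raise ValidationError(f"non-positive {col} for species: {nonpos}")
        df["habitat_breadth"] = pd.to_numeric(df["habitat_breadth"])
        bad_hb = df.loc[~(df["habitat_breadth"] >= 1), "species_id"].tolist()
        if bad_hb:
            raise ValidationError(f"habitat_breadth < 1 for species: {bad_hb}")
        df["foraging_stratum"] = pd.to_numeric(df["foraging_stratum"]).astype(int)
        bad_fs = df.loc[~df["foraging_stratum"].isin([1, 2, 3, 4]), "species_id"]
        if len(bad_fs):
            raise ValidationError(
                f"foraging_stratum outside 1-4 for species: {bad_fs.tolist()}"
            )
        if "diet_score" in df.columns:
            df["diet_score"] = pd.to_numeric(df["diet_score"])

    # -- basic interface ----------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def species_ids(self) -> np.ndarray:
        return self.df["species_id"].to_numpy()

    def subset(self, ids: Iterable[str]) -> "SpeciesTable":
        ids = set(ids)
        keep = self.df["species_id"].isin(ids)
        diet = None
        if self.diet_categories is not None:
            diet = self.diet_categories.loc[
                self.diet_categories.index.isin(ids)
            ]
        return SpeciesTable(self.df.loc[keep].copy(), diet)

    def niche_subset(self, niche: str) -> "SpeciesTable":
        niche = niche.strip().lower()
        if niche not in NICHES:
            raise ValidationError(f"unknown diel niche {niche!r}")
        return self.subset(self.df.loc[self.df["diel_niche"] == niche, "species_id"])

    def with_diet_score(self, scores: pd.Series) -> "SpeciesTable":
        """Return a copy with ``diet_score`` filled from ``scores`` (by id)."""
        df = self.df.copy()
        df["diet_score"] = df["species_id"].map(scores)
        if df["diet_score"].isna().any():
            missing = df.loc[df["diet_score"].isna(), "species_id"].tolist()
            raise ValidationError(f"no diet score for species: {missing}")
        return SpeciesTable(df, self.diet_categories)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpeciesTable):
            return NotImplemented
        return self.df.reset_index(drop=True).equals(other.df.reset_index(drop=True))


def read_species_table(path: str | Path) -> SpeciesTable:
    """Read and validate a species table from CSV.

    The file must have a header naming all required columns; enum columns are
    normalised for case and surrounding whitespace.
    """
    df = pd.read_csv(path)
    return SpeciesTable(df)


def write_species_table(table: SpeciesTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)


def apply_scenario(
    table: SpeciesTable, scenario: ExtinctionScenario | str
) -> tuple[SpeciesTable, SpeciesTable]:
    """Split a table into (survivors, removed) under a scenario.

    Removal depends only on ``iucn_status`` and, for the NT scenario, the
    ``dd_threatened`` flag.  The two return tables partition the input.
    """
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario.upper()]
    mask = scenario.removal_mask(table)
    ids = table.df["species_id"]
    return table.subset(ids[~mask]), table.subset(ids[mask])


@dataclass
class NicheSummary:
    """Per-niche threat summary for one scenario."""

    scenario: str
    table: pd.DataFrame  # niche, n, n_removed, proportion, share_of_table,
    #                      log_odds_vs_nocturnal, se

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"NicheSummary(scenario={self.scenario!r})\n{self.table}"


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def niche_threat_summary(
    table: SpeciesTable, scenario: ExtinctionScenario | str
) -> NicheSummary:
    """Raw per-niche removal proportions and log-odds contrasts vs nocturnal.

    The contrast is ``logit(p_niche) - logit(p_nocturnal)`` with the standard
    two-proportion standard error ``sqrt(sum of 1/cell counts)``.  Niches with
    zero or all species removed get NaN contrasts (flagged, not silently
    dropped); niches absent from the table are omitted.  Model-based contrasts
    (e.g. with genus random effects) are deliberately out of scope — users can
    fit those externally from these raw counts.
    """
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario.upper()]
    mask = scenario.removal_mask(table)
    df = table.df
    rows = []
    for niche in NICHES:
        sel = (df["diel_niche"] == niche).to_numpy()
        n = int(sel.sum())
        if n == 0:
            continue
        k = int((sel & mask).sum())
        rows.append({"niche": niche, "n": n, "n_removed": k, "proportion": k / n})
    out = pd.DataFrame(rows)
    out["share_of_table"] = out["n"] / out["n"].sum()

    noc = out.loc[out["niche"] == "nocturnal"]
    contrasts, ses = [], []
    for _, row in out.iterrows():
        if noc.empty:
            contrasts.append(np.nan)
            ses.append(np.nan)
            continue
        n0, k0 = int(noc["n"].iloc[0]), int(noc["n_removed"].iloc[0])
        n1, k1 = int(row["n"]), int(row["n_removed"])
        cells = (k1, n1 - k1, k0, n0 - k0)
        if row["niche"] == "nocturnal":
            contrasts.append(0.0)
            ses.append(0.0)
        elif 0 in cells:
            contrasts.append(np.nan)
            ses.append(np.nan)
        else:
            contrasts.append(_logit(k1 / n1) - _logit(k0 / n0))
            ses.append(math.sqrt(sum(1.0 / c for c in cells)))
    out["log_odds_vs_nocturnal"] = contrasts
    out["se"] = ses
    return NicheSummary(scenario.name, out)
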