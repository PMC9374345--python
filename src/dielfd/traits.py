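"""Diet ordination and trait transformation.

Diet enters the analysis as semi-quantitative use scores over 10 food
categories.  A continuous diet trait is derived by computing Gower
dissimilarities between species over those categories and extracting the
first axis of a classical principal-coordinates decomposition (PCoA) of the
resulting distance matrix.  The axis is oriented so that the plant/seed pole
is negative, giving a reproducible invertivore-to-herbivore gradient.

The five traits feeding both the trait spectra and the functional dendrogram
are transformed (log10 body mass, log10 litter size, sqrt habitat breadth;
foraging stratum kept on its ordinal 1-4 scale; diet score as-is) and then
z-standardized column-wise with the sample SD (n - 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse.linalg

from .core import PLANT_DIET_CATEGORIES, SpeciesTable

__all__ = [
    "DietOrdination",
    "TransformedTraits",
    "ordinate_diet",
    "transform_traits",
    "gower_distances",
    "TRAIT_COLUMNS",
]

TRAIT_COLUMNS = (
    "log10_body_mass",
    "log10_litter_size",
    "sqrt_habitat_breadth",
    "foraging_stratum",
    "diet_score",
)


def gower_distances(X: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Pairwise Gower dissimilarity over quantitative columns.

    d(i, j) = sum_k w_k |x_ik - x_jk| / range_k / sum_k w_k, with the range
    taken from the observed data.  Zero-range columns carry no information and
    are dropped from the sum with a warning.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if weights is None:
        weights = np.ones(p)
    weights = np.asarray(weights, dtype=float)
    rng = X.max(axis=0) - X.min(axis=0)
    keep = rng > 0
    if not keep.all():
        warnings.warn(
            f"{(~keep).sum()} zero-range column(s) dropped from Gower distance",
            stacklevel=2,
        )
    if not keep.any():
        return np.zeros((n, n))
    Xs = X[:, keep] / rng[keep]
    w = weights[keep]
    D = np.zeros((n, n))
    for k in range(Xs.shape[1]):
        D += w[k] * np.abs(Xs[:, k][:, None] - Xs[:, k][None, :])
    D /= w.sum()
    return D


@dataclass
class DietOrdination:
    """PCoA of the Gower diet-distance matrix.

    ``scores`` holds per-species coordinates on the retained axes (axis 1
    first); ``eigenvalues`` and ``pct_variation`` cover every positive
    eigenvalue (percentages use the positive-eigenvalue sum as denominator, so
    they are <= 100 and non-increasing).
    """

    scores: pd.DataFrame  # index species_id, columns axis_1, axis_2, ...
    eigenvalues: np.ndarray
    pct_variation: np.ndarray

    @property
    def axis1(self) -> pd.Series:
        return self.scores["axis_1"]

    def report(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "axis": np.arange(1, len(self.eigenvalues) + 1),
                "eigenvalue": self.eigenvalues,
                "pct_variation": self.pct_variation,
            }
        )


def ordinate_diet(
    diet_table: pd.DataFrame,
    n_axes: int = 2,
    plant_categories: tuple[str, ...] | None = None,
) -> DietOrdination:
    """Classical PCoA of Gower distances over diet categories.

    No eigenvalue correction is applied to the (generally non-Euclidean)
    Gower matrix: negative eigenvalues are simply excluded from the
    percent-variation denominator.  Axis 1 is sign-fixed so species relying on
    plant material and seeds score negative.

    Parameters
    ----------
    diet_table
        species × category frame of non-negative semi-quantitative values,
        indexed by species id.
    n_axes
        number of leading axes to return (at most the number of positive
        eigenvalues).
    plant_categories
        column names forming the herbivory pole; defaults to categories 7-10
        when present.
    """
    if len(diet_table) < 3:
        raise ValueError("diet ordination needs at least 3 species")
    X = diet_table.to_numpy(dtype=float)
    if np.ptp(X, axis=0).max() == 0:
        raise ValueError("degenerate diet table: all rows identical")
    D = gower_distances(X)

    # classical PCoA: double-center -0.5 * D^2 (O(n^2) broadcast form)
    D2 = D**2
    n = len(D)
    row_mean = D2.mean(axis=1)
    B = -0.5 * (D2 - row_mean[:, None] - row_mean[None, :] + D2.mean())
    B = (B + B.T) / 2.0

    eig_all = scipy.linalg.eigvalsh(B)[::-1]
    tol = 1e-10 * max(eig_all[0], 1.0)
    eigval = eig_all[eig_all > tol]
    if eigval.size == 0:
        raise ValueError("degenerate diet distances: no positive eigenvalues")
    pct = 100.0 * eigval / eigval.sum()

    # eigenvectors only for the requested leading axes (Lanczos for large n)
    k = min(n_axes, len(eigval))
    if n > 500:
        w, V = scipy.sparse.linalg.eigsh(B, k=k, which="LA")
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
    else:
        w, V = np.linalg.eigh(B)
        order = np.argsort(w)[::-1][:k]
        w, V = w[order], V[:, order]
    scores = V * np.sqrt(np.clip(w, 0.0, None))
    cols = [f"axis_{i + 1}" for i in range(k)]
    sc = pd.DataFrame(scores, index=diet_table.index, columns=cols)

    if plant_categories is None:
        plant_categories = tuple(
            c for c in PLANT_DIET_CATEGORIES if c in diet_table.columns
        )
    if plant_categories:
        plant_share = diet_table[list(plant_categories)].sum(axis=1).to_numpy(float)
        total = X.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            plant_share = np.where(total > 0, plant_share / total, 0.0)
        if plant_share.std() > 0:
            r = np.corrcoef(sc["axis_1"], plant_share)[0, 1]
            if np.isfinite(r) and r > 0:
                sc["axis_1"] *= -1.0
    return DietOrdination(sc, eigval, pct)


@dataclass
class TransformedTraits:
    """Transformed, optionally standardized species × 5 trait matrix.

    Stores per-column means/SDs so the standardization is invertible.
    """

    values: pd.DataFrame  # index species_id, columns TRAIT_COLUMNS
    means: pd.Series
    sds: pd.Series
    standardized: bool = True

    @property
    def species_ids(self) -> np.ndarray:
        return self.values.index.to_numpy()

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def subset(self, ids) -> "TransformedTraits":
        return TransformedTraits(
            self.values.loc[list(ids)], self.means, self.sds, self.standardized
        )

    def inverse_transform(self) -> pd.DataFrame:
        """Recover the raw traits from the stored parameters."""
        vals = self.values
        if self.standardized:
            vals = vals * self.sds + self.means
        out = pd.DataFrame(index=vals.index)
        out["body_mass_g"] = 10.0 ** vals["log10_body_mass"]
        out["litter_size"] = 10.0 ** vals["log10_litter_size"]
        out["habitat_breadth"] = vals["sqrt_habitat_breadth"] ** 2
        out["foraging_stratum"] = vals["foraging_stratum"]
        out["diet_score"] = vals["diet_score"]
        return out


def transform_traits(
    table: SpeciesTable,
    diet: DietOrdination | pd.Series | None = None,
    standardize: bool = True,
) -> TransformedTraits:
    """Build the 5-column transformed trait matrix.

    ``diet`` may be a :class:`DietOrdination` (axis 1 used), a per-species
    Series, or None when the table already carries ``diet_score``.
    """
    df = table.df.set_index("species_id")
    if diet is None:
        if "diet_score" not in df.columns or df["diet_score"].isna().any():
            raise ValueError("table has no complete diet_score and no diet given")
        diet_score = df["diet_score"]
    elif isinstance(diet, DietOrdination):
        diet_score = diet.axis1.reindex(df.index)
    else:
        diet_score = pd.Series(diet).reindex(df.index)
    if diet_score.isna().any():
        missing = diet_score.index[diet_score.isna()].tolist()
        raise ValueError(f"no diet score for species: {missing}")

    bad = df.index[~(df["body_mass_g"] > 0)].tolist()
    if bad:
        raise ValueError(f"non-positive body mass for species: {bad}")

    out = pd.DataFrame(
        {
            "log10_body_mass": np.log10(df["body_mass_g"].to_numpy(float)),
            "log10_litter_size": np.log10(df["litter_size"].to_numpy(float)),
            "sqrt_habitat_breadth": np.sqrt(df["habitat_breadth"].to_numpy(float)),
            "foraging_stratum": df["foraging_stratum"].to_numpy(float),
            "diet_score": diet_score.to_numpy(float),
        },
        index=df.index,
    )
    means = out.mean()
    sds = out.std(ddof=1)
    if standardize:
        if (sds == 0).any():
            zero = sds.index[sds == 0].tolist()
            raise ValueError(f"zero-variance trait column(s): {zero}")
        out = (out - means) / sds
    return TransformedTraits(out, means, sds, standardize)
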