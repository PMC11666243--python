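"""Per-lipid association with the aggregation phenotype and class-level enrichment.

Each lipid species' replicate-averaged log-abundance across a panel of
perturbations is regressed (OLS with intercept) on the perturbations'
ProteoStat phenotype; the coefficient of determination R² summarizes how
tightly the species tracks the phenotype.  Class-level enrichment then asks
whether the R² values of a lipid class (e.g. sphingomyelins or cholesterol
esters) are distributed differently from the R² values of all lipids, via a
two-sample two-sided Kolmogorov–Smirnov test.  Following the screen's
reporting convention, the reference sample includes the class's own members
and no multiple-testing correction is applied across classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "LipidFit",
    "lipid_r2",
    "fit_all",
    "class_ks",
    "LipidPhenotypeModel",
    "LipidResults",
]

META_COLS = ("species_id", "lipid_class")


@dataclass
class LipidFit:
    species_id: str
    slope: float
    intercept: float
    r2: float


def lipid_r2(abundance, phenotype, species_id: str = "") -> LipidFit:
    """OLS fit (with intercept) of species abundance on the phenotype.

    R² equals the squared Pearson correlation.  A constant phenotype is an
    error (the regression is undefined); a constant abundance yields R² = 0
    with a warning.
    """
    y = np.asarray(abundance, dtype=float)
    x = np.asarray(phenotype, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("abundance and phenotype must be equal-length vectors")
    if y.size < 3:
        raise ValueError("need >= 3 perturbations for a meaningful R^2")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in regression inputs")
    if np.ptp(x) == 0.0:
        raise ValueError("constant phenotype: regression undefined")
    if np.ptp(y) == 0.0:
        warnings.warn(f"constant abundance for {species_id or 'species'}; R^2 = 0",
                      stacklevel=2)
        return LipidFit(species_id, 0.0, float(y[0]), 0.0)
    fit = sps.linregress(x, y)
    return LipidFit(species_id, float(fit.slope), float(fit.intercept),
                    float(fit.rvalue ** 2))


def fit_all(table: pd.DataFrame, phenotype: pd.Series,
            subset: list[str] | None = None) -> pd.DataFrame:
    """Per-species OLS fits over the (optionally subset) perturbation panel.

    ``table`` holds ``species_id, lipid_class`` plus one column per
    perturbation; ``phenotype`` is indexed by perturbation id.  ``subset``
    restricts the regression to a named core set of perturbations.
    """
    pert_cols = [c for c in table.columns if c not in META_COLS]
    if subset is not None:
        missing = [p for p in subset if p not in pert_cols]
        if missing:
            raise ValueError(f"perturbations not in table: {missing}")
        pert_cols = list(subset)
    missing = [p for p in pert_cols if p not in phenotype.index]
    if missing:
        raise ValueError(f"perturbations missing from phenotype: {missing}")
    x = phenotype.loc[pert_cols]
    rows = []
    for _, row in table.iterrows():
        fit = lipid_r2(row[pert_cols].to_numpy(dtype=float), x,
                       species_id=row["species_id"])
        rows.append({"species_id": fit.species_id,
                     "lipid_class": row["lipid_class"], "slope": fit.slope,
                     "intercept": fit.intercept, "r2": fit.r2})
    return pd.DataFrame(rows)


def _ks_statistic_vs_all(subset_sorted: np.ndarray, all_sorted: np.ndarray) -> float:
    """sup |ECDF(subset) - ECDF(all)| where subset values come from ``all``."""
    n = all_sorted.size
    f_all = np.arange(1, n + 1) / n
    f_sub = np.searchsorted(subset_sorted, all_sorted, side="right") / subset_sorted.size
    return float(np.abs(f_sub - f_all).max())


def _exact_inclusive_p(class_vals: np.ndarray, all_vals: np.ndarray) -> float:
    """Exact p by enumerating which members of the full vector form the class.

    The class sample overlaps its reference (all lipids), so the usual
    independent-two-sample exact distribution does not apply; instead every
    C(n, k) assignment of k class labels is enumerated and p is the fraction
    of assignments whose D(class, all) reaches the observed one.
    """
    from itertools import combinations

    xs = np.sort(all_vals)
    k = class_vals.size
    d_obs = _ks_statistic_vs_all(np.sort(class_vals), xs)
    count = total = 0
    for combo in combinations(range(xs.size), k):
        d = _ks_statistic_vs_all(xs[list(combo)], xs)
        count += d >= d_obs - 1e-12
        total += 1
    return count / total


#: enumeration budget for the exact inclusive-reference p-value
MAX_EXACT_ASSIGNMENTS = 200_000


def class_ks(fits: pd.DataFrame, inclusive: bool = True,
             min_class_size: int = 2) -> pd.DataFrame:
    """Two-sample two-sided K-S test of each class's R² values versus all lipids.

    With ``inclusive=True`` (default, matching the reporting convention) the
    reference sample is the full R² vector including the class's own
    members; because the samples then overlap, the exact small-sample
    p-value enumerates the assignments of class labels to the pooled values
    (used when the class has <= 10 members, the R² values are tie-free, and
    the number of assignments is within :data:`MAX_EXACT_ASSIGNMENTS`),
    falling back to the asymptotic approximation otherwise.  With
    ``inclusive=False`` the class is tested against the complement using the
    standard exact two-sample distribution under the same small-sample,
    tie-free condition.  Classes with fewer than ``min_class_size`` members
    are skipped with a warning.  Returns ``lipid_class, n_species, ks_d, p``.
    """
    from math import comb

    all_r2 = fits["r2"].to_numpy(dtype=float)
    rows = []
    for cls, grp in fits.groupby("lipid_class", sort=True):
        r2 = grp["r2"].to_numpy(dtype=float)
        if r2.size < min_class_size:
            warnings.warn(f"class {cls!r} has {r2.size} species; skipped",
                          stacklevel=2)
            continue
        if inclusive:
            d = _ks_statistic_vs_all(np.sort(r2), np.sort(all_r2))
            tie_free = np.unique(all_r2).size == all_r2.size
            if (min(r2.size, all_r2.size) <= 10 and tie_free
                    and comb(all_r2.size, r2.size) <= MAX_EXACT_ASSIGNMENTS):
                p = _exact_inclusive_p(r2, all_r2)
            else:
                p = float(sps.ks_2samp(r2, all_r2, alternative="two-sided",
                                       method="asymp").pvalue)
        else:
            ref = fits.loc[fits["lipid_class"] != cls, "r2"].to_numpy(dtype=float)
            pooled = np.concatenate([r2, ref])
            tie_free = np.unique(pooled).size == pooled.size
            method = ("exact" if (min(r2.size, ref.size) <= 10 and tie_free)
                      else "asymp")
            res = sps.ks_2samp(r2, ref, alternative="two-sided", method=method)
            d, p = float(res.statistic), float(res.pvalue)
        rows.append({"lipid_class": cls, "n_species": int(r2.size),
                     "ks_d": float(d), "p": float(p)})
    return pd.DataFrame(rows)


class LipidPhenotypeModel:
    """Association of lipid species abundance with a perturbation phenotype.

    Parameters
    ----------
    table
        Species x perturbation log-abundance table (``species_id,
        lipid_class`` plus one column per perturbation), values normalized
        to a non-targeting control.
    phenotype
        Aggregation phenotype per perturbation (replicate-averaged,
        NT-normalized), indexed by perturbation id.
    core_set
        Optional list of perturbation ids to restrict the regressions to.
    """

    def __init__(self, table: pd.DataFrame, phenotype: pd.Series,
                 core_set: list[str] | None = None):
        for c in META_COLS:
            if c not in table.columns:
                raise ValueError(f"lipid table missing column {c!r}")
        if table["lipid_class"].isna().any():
            raise ValueError("missing lipid class labels")
        self.table = table.reset_index(drop=True)
        self.phenotype = phenotype
        self.core_set = core_set

    @classmethod
    def from_csv(cls, table_path, phenotype_path, **kwargs) -> "LipidPhenotypeModel":
        from . import io
        return cls(io.read_lipid_csv(table_path),
                   io.read_phenotype_csv(phenotype_path), **kwargs)

    def fit(self, inclusive_reference: bool = True) -> "LipidResults":
        fits = fit_all(self.table, self.phenotype, subset=self.core_set)
        classes = class_ks(fits, inclusive=inclusive_reference)
        return LipidResults(self, fits, classes)


class LipidResults:
    """Per-species fits and per-class K-S enrichment of a lipid panel."""

    def __init__(self, model: LipidPhenotypeModel, species_fits: pd.DataFrame,
                 class_enrichment: pd.DataFrame):
        self.model = model
        self.species_fits = species_fits
        self.class_enrichment = class_enrichment

    def max_r2(self, lipid_class: str) -> float:
        """Largest species R² within one class."""
        sel = self.species_fits["lipid_class"] == lipid_class
        if not sel.any():
            raise KeyError(f"no species in class {lipid_class!r}")
        return float(self.species_fits.loc[sel, "r2"].max())

    def summary(self) -> str:
        lines = [
            "Lipid class association with aggregation phenotype",
            "==================================================",
            f"species             : {len(self.species_fits)}",
            f"perturbations       : {len(self.model.core_set) if self.model.core_set else len([c for c in self.model.table.columns if c not in META_COLS])}",
            "",
            self.class_enrichment.sort_values("p").to_string(
                index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)
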