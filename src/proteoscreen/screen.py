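"""Gene-level enrichment statistics for sorted-bin screen counts.

Counts from the ProteoStat-high and ProteoStat-low bins are size-factor
normalized (median-of-ratios), converted to per-guide log2 fold changes,
aggregated to a per-gene median, and tested against a null built by
resampling non-targeting (NT) guides — the screen's designed negative
controls.  Benjamini–Hochberg correction yields a gene-level FDR.

The public surface is the :class:`SortedBinScreen` model whose ``fit``
returns a :class:`ScreenResults`; the stage functions
(:func:`normalize_counts`, :func:`guide_lfc`, :func:`gene_stats`) are also
usable directly.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SortedBinScreen",
    "ScreenResults",
    "normalize_counts",
    "guide_lfc",
    "gene_stats",
    "count_columns",
]

META_COLS = ("guide_id", "gene", "is_nt")


def count_columns(counts: pd.DataFrame) -> list[str]:
    """Return the bin-count columns (``high_rep*``/``low_rep*``) in order."""
    cols = [c for c in counts.columns
            if c.startswith("high_rep") or c.startswith("low_rep")]
    if not cols:
        raise ValueError("no high_rep*/low_rep* count columns found")
    return cols


def replicate_ids(counts: pd.DataFrame) -> list[str]:
    reps = sorted({c.split("_rep", 1)[1] for c in count_columns(counts)}, key=int)
    for r in reps:
        for side in ("high", "low"):
            if f"{side}_rep{r}" not in counts.columns:
                raise ValueError(f"missing column {side}_rep{r}")
    return reps


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Median-of-ratios size-factor normalization across all bin samples.

    The size factor of each sample is the median, over guides detected in
    every sample, of the ratio of the guide's count to its geometric mean
    across samples.  Counts are divided by the sample's factor.
    """
    cols = count_columns(counts)
    mat = counts[cols].to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no guide has nonzero counts in every sample; median-of-ratios "
            "undefined — rerun with total-count normalization (use_total=True "
            "is not enabled by default)")
    ref = mat[all_nonzero]
    log_geo_mean = np.log(ref).mean(axis=1)
    factors = np.exp(np.median(np.log(ref) - log_geo_mean[:, None], axis=0))
    out = counts.copy()
    out[cols] = mat / factors
    return out


def guide_lfc(norm_counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.Series:
    """Per-guide log2(high/low), averaged over replicates.

    A pseudocount is added to both bins before the log so the statistic is
    finite even for guides absent from one bin.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    reps = replicate_ids(norm_counts)
    lfcs = []
    for r in reps:
        hi = norm_counts[f"high_rep{r}"].to_numpy(dtype=float)
        lo = norm_counts[f"low_rep{r}"].to_numpy(dtype=float)
        lfcs.append(np.log2(hi + pseudocount) - np.log2(lo + pseudocount))
    out = pd.Series(np.mean(lfcs, axis=0), name="lfc")
    if "guide_id" in norm_counts.columns:
        out.index = pd.Index(norm_counts["guide_id"], name="guide_id")
    return out


def _null_median_table(nt_lfcs: np.ndarray, sizes: np.ndarray,
                       n_perm: int, rng: np.random.Generator) -> dict[int, np.ndarray]:
    """For each distinct guides-per-gene size k, n_perm medians of k NT LFCs
    resampled with replacement.  Shared across genes of the same size."""
    table = {}
    for k in np.unique(sizes):
        draws = rng.choice(nt_lfcs, size=(n_perm, int(k)), replace=True)
        table[int(k)] = np.median(draws, axis=1)
    return table


def gene_stats(
    lfcs: pd.Series,
    gene_map: pd.Series,
    nt_flags: pd.Series,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Per-gene median LFC, NT-resampling permutation p, and BH FDR.

    The null for a gene with ``k`` guides is the distribution of medians of
    ``k`` NT-guide LFCs drawn with replacement; the two-sided p-value is
    ``(b + 1) / (n_perm + 1)`` with ``b`` the number of null medians at least
    as extreme in absolute value, so p is never exactly zero.
    """
    lfc = np.asarray(lfcs, dtype=float)
    gene = np.asarray(gene_map)
    is_nt = np.asarray(nt_flags, dtype=bool)
    nt_lfcs = lfc[is_nt]
    if nt_lfcs.size == 0:
        raise ValueError("no non-targeting guides: NT null undefined")
    if nt_lfcs.size < 50:
        warnings.warn(f"only {nt_lfcs.size} NT guides; permutation null may be "
                      "coarse (>= 50 recommended)", stacklevel=2)

    grp = pd.Series(lfc[~is_nt]).groupby(pd.Series(gene[~is_nt]))
    obs = grp.median()
    sizes = grp.size()
    if (sizes == 0).any():
        raise ValueError("gene with zero guides")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nulls = _null_median_table(nt_lfcs, sizes.to_numpy(), n_perm, rng)
    pvals = np.empty(len(obs))
    for i, (g, m) in enumerate(obs.items()):
        null = nulls[int(sizes[g])]
        b = int(np.count_nonzero(np.abs(null) >= abs(m)))
        pvals[i] = (b + 1) / (n_perm + 1)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({"gene": obs.index, "lfc": obs.to_numpy(),
                         "p": pvals, "fdr": fdr,
                         "n_guides": sizes.loc[obs.index].to_numpy()}
                        ).reset_index(drop=True)


class SortedBinScreen:
    """Gene-enrichment model for a sorted-bin screen count table.

    Parameters
    ----------
    counts
        Tidy table with columns ``guide_id, gene, is_nt`` and per-replicate
        ``high_rep{r}``/``low_rep{r}`` integer counts.
    pseudocount
        Added to both bins before the log2 ratio.
    """

    def __init__(self, counts: pd.DataFrame, pseudocount: float = 0.5):
        missing = [c for c in META_COLS if c not in counts.columns]
        if missing:
            raise ValueError(f"counts table missing columns: {missing}")
        dup = counts.loc[~counts["is_nt"], "guide_id"].duplicated()
        if dup.any():
            raise ValueError("duplicated guide ids")
        count_columns(counts)  # validates presence
        self.counts = counts.reset_index(drop=True)
        self.pseudocount = float(pseudocount)

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "SortedBinScreen":
        from . import io
        return cls(io.read_counts(path), **kwargs)

    def fit(self, n_perm: int = 10_000, seed: int = 0) -> "ScreenResults":
        norm = normalize_counts(self.counts)
        lfcs = guide_lfc(norm, self.pseudocount)
        stats = gene_stats(lfcs, self.counts["gene"], self.counts["is_nt"],
                           n_perm=n_perm, seed=seed)
        return ScreenResults(self, stats, lfcs, n_perm=n_perm, seed=seed)


class ScreenResults:
    """Fitted gene-level statistics of a :class:`SortedBinScreen`.

    Attributes
    ----------
    gene_stats : pandas.DataFrame
        Columns ``gene, lfc, p, fdr, n_guides``.
    guide_lfcs : pandas.Series
        Per-guide replicate-averaged log2 fold changes (NT guides included).
    """

    def __init__(self, model: SortedBinScreen, stats: pd.DataFrame,
                 guide_lfcs: pd.Series, n_perm: int, seed: int):
        self.model = model
        self.gene_stats = stats
        self.guide_lfcs = guide_lfcs
        self.n_perm = n_perm
        self.seed = seed

    def call_hits(self, alpha: float = 0.05, rule: str = "product") -> pd.Series:
        """Hit labels {'up', 'down', 'none'} per gene; see scoring module."""
        from .scoring import volcano_hit_call, fdr_hit_call
        if rule == "product":
            return volcano_hit_call(self.gene_stats, alpha=alpha)
        if rule == "fdr":
            return fdr_hit_call(self.gene_stats, alpha=alpha)
        raise ValueError(f"unknown hit rule {rule!r}")

    def prerank_scores(self, fdr_floor: float | None = None) -> pd.DataFrame:
        from .scoring import prerank_score
        if fdr_floor is None:
            fdr_floor = 1.0 / (self.n_perm + 1)
        return prerank_score(self.gene_stats, fdr_floor=fdr_floor)

    def summary(self, alpha: float = 0.05) -> str:
        hits = self.call_hits(alpha=alpha, rule="fdr")
        n_up = int((hits == "up").sum())
        n_down = int((hits == "down").sum())
        lines = [
            "Sorted-bin screen gene enrichment",
            "=================================",
            f"genes tested        : {len(self.gene_stats)}",
            f"guides (targeting)  : {int((~self.model.counts['is_nt']).sum())}",
            f"guides (non-target) : {int(self.model.counts['is_nt'].sum())}",
            f"permutations        : {self.n_perm}",
            f"hits at FDR<{alpha:g}    : {n_up} up, {n_down} down",
        ]
        top = self.gene_stats.nsmallest(10, "fdr")
        lines.append("")
        lines.append(top.to_string(index=False,
                                   float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)
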