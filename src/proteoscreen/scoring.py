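"""Hit calling, the combined effect/confidence prerank score, and preranked GSEA.

Two hit rules are provided: the plain ``FDR < alpha`` filter split by LFC
sign, and the volcano product rule, under which a gene is a hit when
``|log2FC| * (-log10 FDR)`` reaches ``-log10(alpha)`` — the hyperbola drawn
on the screen's volcano plot.

For ranking, each gene receives a score that weights effect size and
confidence equally by standardizing both::

    score = (|LFC|/sigma_LFC + nlFDR/sigma_nlFDR) * D,   nlFDR = log10(1/FDR)

where the sigmas are sample standard deviations over the whole gene table
and D = +/-1 carries the sign of the LFC.  Preranked GSEA on this score uses
the weighted Kolmogorov running-sum statistic with a gene-label permutation
null, normalized enrichment scores, and sign-stratified nominal p and FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "volcano_hit_call",
    "fdr_hit_call",
    "prerank_score",
    "enrichment_score",
    "gsea_prerank",
]


def _check_alpha(alpha: float) -> None:
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")


def fdr_hit_call(stats: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Label genes {'up','down','none'} by FDR < alpha, direction from LFC."""
    _check_alpha(alpha)
    hit = stats["fdr"].to_numpy() < alpha
    return _directional_labels(stats, hit)


def volcano_hit_call(stats: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Product-rule hit labels: |LFC| * (-log10 FDR) >= -log10(alpha).

    The boundary is the constant-product hyperbola through (|LFC|=1,
    FDR=alpha); genes on the curve count as hits.
    """
    _check_alpha(alpha)
    lfc = stats["lfc"].to_numpy(dtype=float)
    fdr = stats["fdr"].to_numpy(dtype=float)
    if not np.isfinite(lfc).all():
        raise ValueError("non-finite LFC")
    if ((fdr <= 0) | (fdr > 1)).any():
        raise ValueError("FDR must lie in (0, 1]")
    product = np.abs(lfc) * (-np.log10(fdr))
    hit = product >= -np.log10(alpha)
    return _directional_labels(stats, hit)


def _directional_labels(stats: pd.DataFrame, hit: np.ndarray) -> pd.Series:
    lfc = stats["lfc"].to_numpy(dtype=float)
    labels = np.where(hit & (lfc > 0), "up",
                      np.where(hit & (lfc < 0), "down", "none"))
    return pd.Series(labels, index=stats.index, name="hit")


def prerank_score(stats: pd.DataFrame, fdr_floor: float = 1e-12) -> pd.DataFrame:
    """Signed, standardized effect+confidence score per gene.

    FDR values are floored at ``fdr_floor`` before the log so nlFDR stays
    finite; both standard deviations use the n-1 denominator over the full
    table.  D is +1 when LFC is exactly 0 (the score is then driven by
    nlFDR alone).
    """
    if len(stats) < 2:
        raise ValueError("need >= 2 genes to define the score sigmas")
    if fdr_floor <= 0:
        raise ValueError("fdr_floor must be positive")
    lfc = stats["lfc"].to_numpy(dtype=float)
    fdr = np.maximum(stats["fdr"].to_numpy(dtype=float), fdr_floor)
    nlfdr = np.log10(1.0 / fdr)
    sigma_lfc = float(np.std(lfc, ddof=1))
    sigma_nlfdr = float(np.std(nlfdr, ddof=1))
    if sigma_lfc == 0.0 or sigma_nlfdr == 0.0:
        raise ValueError("degenerate constant column: score sigma is zero")
    d = np.where(lfc < 0, -1.0, 1.0)
    score = (np.abs(lfc) / sigma_lfc + nlfdr / sigma_nlfdr) * d
    return pd.DataFrame({"gene": stats["gene"].to_numpy(), "lfc": lfc,
                         "fdr": fdr, "nlfdr": nlfdr, "score": score})


# ---------------------------------------------------------------------------
# Preranked GSEA


def _rank_scores(scores: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Descending score order, ties broken by gene identifier."""
    df = scores[["gene", "score"]].copy()
    df = df.sort_values(["score", "gene"], ascending=[False, True],
                        kind="mergesort")
    return df["gene"].to_numpy(), df["score"].to_numpy(dtype=float)


def enrichment_score(ranked_scores: np.ndarray, hit_mask: np.ndarray,
                     p: float = 1.0) -> float:
    """Weighted Kolmogorov running-sum enrichment score of one gene set.

    ``ranked_scores`` are the scores in ranked (descending) order and
    ``hit_mask`` flags set members at their rank positions.  Hits step the
    running sum up by ``|score|^p`` (normalized over hits), misses step it
    down by ``1/(N - N_hit)``; the ES is the deviation of largest magnitude.
    """
    n = ranked_scores.size
    n_hit = int(hit_mask.sum())
    if n_hit == 0:
        raise ValueError("empty gene set after intersection with scored genes")
    if n_hit == n:
        raise ValueError("gene set covers all scored genes")
    w = np.abs(ranked_scores) ** p
    w_hit = np.where(hit_mask, w, 0.0)
    total = w_hit.sum()
    if total == 0.0:  # all member scores exactly zero: fall back to uniform
        inc = hit_mask / n_hit
    else:
        inc = w_hit / total
    dec = (~hit_mask) / (n - n_hit)
    running = np.cumsum(inc - dec)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def _null_es_batch(ranked_scores: np.ndarray, n_hit: int, n_perm: int,
                   p: float, rng: np.random.Generator) -> np.ndarray:
    """ES under random gene-label assignment of the set, vectorized."""
    n = ranked_scores.size
    w = np.abs(ranked_scores) ** p
    # random n_hit positions per permutation, without replacement
    keys = rng.random((n_perm, n))
    pos = np.argpartition(keys, n_hit - 1, axis=1)[:, :n_hit]
    pos.sort(axis=1)
    wh = w[pos]
    tot = wh.sum(axis=1, keepdims=True)
    uniform = tot[:, 0] == 0.0
    cumw = np.cumsum(wh, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cumw = np.where(uniform[:, None],
                        np.arange(1, n_hit + 1) / n_hit, cumw / tot)
    j = np.arange(1, n_hit + 1)
    miss = 1.0 / (n - n_hit)
    # running sum right after hit j and right before hit j
    after = cumw - (pos + 1 - j) * miss
    before = np.concatenate(
        [np.zeros((n_perm, 1)), cumw[:, :-1]], axis=1) - (pos + 1 - j) * miss
    hi = after.max(axis=1)
    lo = np.minimum(before.min(axis=1), 0.0)
    return np.where(hi >= -lo, hi, lo)


@dataclass
class EnrichmentResult:
    name: str
    size: int
    es: float
    nes: float
    p: float
    fdr: float
    leading_edge: list[str]


def gsea_prerank(
    scores: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    n_perm: int = 1000,
    p: float = 1.0,
    min_size: int = 5,
    max_size: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked GSEA over a gene-set collection.

    Genes are ranked by descending score (ties broken by identifier); each
    set's ES is normalized by the mean |null ES| of the same sign from
    ``n_perm`` gene-label permutations.  Nominal p is sign-stratified with a
    +1 permutation-floor correction; FDR follows the standard preranked
    procedure comparing each NES against the pooled null NES distribution of
    the same sign.

    Returns a table sorted by FDR with columns ``name, size, es, nes, p,
    fdr, leading_edge``.
    """
    ranked_genes, ranked_scores = _rank_scores(scores)
    gene_pos = {g: i for i, g in enumerate(ranked_genes)}
    rng = np.random.default_rng(seed)

    kept: list[tuple[str, np.ndarray]] = []
    for name, members in gene_sets.items():
        pos = np.array(sorted({gene_pos[g] for g in members if g in gene_pos}),
                       dtype=int)
        if not (min_size <= pos.size <= max_size):
            continue
        if pos.size == ranked_genes.size:
            raise ValueError(f"gene set {name!r} covers all scored genes")
        kept.append((name, pos))
    if not kept:
        return pd.DataFrame(columns=["name", "size", "es", "nes", "p", "fdr",
                                     "leading_edge"])

    n = ranked_genes.size
    null_by_size: dict[int, np.ndarray] = {}
    rows = []
    null_nes_pool: list[np.ndarray] = []
    for name, pos in kept:
        mask = np.zeros(n, bool)
        mask[pos] = True
        es = enrichment_score(ranked_scores, mask, p=p)
        k = pos.size
        if k not in null_by_size:
            null_by_size[k] = _null_es_batch(ranked_scores, k, n_perm, p, rng)
        null = null_by_size[k]
        same_sign = null >= 0 if es >= 0 else null < 0
        m = int(same_sign.sum())
        if m == 0:
            nes, pval = np.nan, 1.0
            null_nes = np.array([])
        else:
            denom = np.abs(null[same_sign]).mean()
            nes = es / denom if denom > 0 else np.nan
            b = int(np.count_nonzero(np.abs(null[same_sign]) >= abs(es)))
            pval = (b + 1) / (m + 1)
            null_nes = null[same_sign] / denom
        null_nes_pool.append(null_nes)
        running_best = _leading_edge(ranked_genes, ranked_scores, mask, es, p)
        rows.append({"name": name, "size": k, "es": es, "nes": nes,
                     "p": pval, "leading_edge": running_best})

    res = pd.DataFrame(rows)
    pooled = np.concatenate(null_nes_pool) if null_nes_pool else np.array([])
    res["fdr"] = _gsea_fdr(res["nes"].to_numpy(), pooled)
    res = res[["name", "size", "es", "nes", "p", "fdr", "leading_edge"]]
    return res.sort_values("fdr", kind="mergesort").reset_index(drop=True)


def _leading_edge(ranked_genes: np.ndarray, ranked_scores: np.ndarray,
                  mask: np.ndarray, es: float, p: float) -> list[str]:
    """Set members on the ES side of the peak of the running sum."""
    n = ranked_genes.size
    n_hit = int(mask.sum())
    w = np.abs(ranked_scores) ** p
    w_hit = np.where(mask, w, 0.0)
    tot = w_hit.sum()
    inc = w_hit / tot if tot > 0 else mask / n_hit
    running = np.cumsum(inc - (~mask) / (n - n_hit))
    peak = int(np.argmax(np.abs(running)))
    if es >= 0:
        sel = mask.copy()
        sel[peak + 1:] = False
    else:
        sel = mask.copy()
        sel[:peak] = False
    return list(ranked_genes[sel])


def _gsea_fdr(nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """Sign-stratified FDR: pooled null-NES tail mass over observed tail mass."""
    q = np.ones_like(nes, dtype=float)
    for sign in (1, -1):
        obs_side = (nes >= 0) if sign > 0 else (nes < 0)
        null_side = null_nes[(null_nes >= 0) if sign > 0 else (null_nes < 0)]
        if not obs_side.any():
            continue
        for i in np.flatnonzero(obs_side):
            v = abs(nes[i])
            if np.isnan(v):
                q[i] = 1.0
                continue
            null_frac = (np.count_nonzero(np.abs(null_side) >= v) / null_side.size
                         if null_side.size else 1.0)
            obs_frac = (np.count_nonzero(np.abs(nes[obs_side]) >= v)
                        / obs_side.sum())
            q[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0
    return q
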