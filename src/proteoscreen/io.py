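"""Plain-text readers and writers for the pipeline's interchange formats.

All tables travel as TSV/CSV with documented headers:

* screen counts — TSV with ``guide_id, gene, is_nt`` then ``high_rep{r}``
  and ``low_rep{r}`` integer columns;
* lipid tables — CSV with ``species_id, lipid_class`` then one column per
  perturbation; phenotype — two-column CSV ``perturbation, proteostat``;
* gene sets — GMT (name, description, then members, tab-separated);
* MAGeCK-style gene summaries — gene-level screen output with ``neg|``/
  ``pos|`` FDR columns, collapsed here to one signed LFC and a single
  two-sided FDR (the smaller of the directional FDRs).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_counts", "write_counts",
    "read_lipid_csv", "write_lipid_csv",
    "read_phenotype_csv", "write_phenotype_csv",
    "read_gmt", "write_gmt",
    "read_mageck_gene_summary",
    "write_results",
]

COUNT_META = ["guide_id", "gene", "is_nt"]


def _require(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required column(s): {missing}")


def read_counts(path) -> pd.DataFrame:
    """Read a screen count TSV; validates columns, types, and unique guides."""
    df = pd.read_csv(path, sep="\t", comment="#")
    _require(df, COUNT_META, "count table")
    bins = [c for c in df.columns
            if c.startswith("high_rep") or c.startswith("low_rep")]
    if not bins:
        raise ValueError("count table has no high_rep*/low_rep* columns")
    if df["guide_id"].duplicated().any():
        dups = df.loc[df["guide_id"].duplicated(), "guide_id"].head(3).tolist()
        raise ValueError(f"duplicated guide ids (e.g. {dups})")
    df["is_nt"] = df["is_nt"].astype(bool)
    for c in bins:
        vals = df[c].to_numpy()
        if not np.allclose(vals, np.round(vals)):
            raise ValueError(f"non-integral counts in column {c!r}")
        df[c] = df[c].astype(np.int64)
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    _require(counts, COUNT_META, "count table")
    counts.to_csv(path, sep="\t", index=False)


def read_lipid_csv(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    _require(df, ["species_id", "lipid_class"], "lipid table")
    if df["species_id"].duplicated().any():
        raise ValueError("duplicated species ids")
    return df


def write_lipid_csv(table: pd.DataFrame, path) -> None:
    _require(table, ["species_id", "lipid_class"], "lipid table")
    table.to_csv(path, index=False)


def read_phenotype_csv(path) -> pd.Series:
    df = pd.read_csv(path, comment="#")
    _require(df, ["perturbation"], "phenotype table")
    value_cols = [c for c in df.columns if c != "perturbation"]
    if len(value_cols) != 1:
        raise ValueError("phenotype CSV must have exactly two columns")
    s = df.set_index("perturbation")[value_cols[0]].astype(float)
    s.name = value_cols[0]
    return s


def write_phenotype_csv(phenotype: pd.Series, path) -> None:
    df = phenotype.rename_axis("perturbation").reset_index()
    df.to_csv(path, index=False)


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection: name, description, members per line."""
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line {lineno}: need name, description and "
                             "at least one member")
        name = parts[0]
        if name in sets:
            raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
        sets[name] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_mageck_gene_summary(path) -> pd.DataFrame:
    """Ingest a MAGeCK-style gene summary into ``gene, lfc, fdr, direction``.

    The two one-sided FDR columns (``neg|fdr``, ``pos|fdr``) are collapsed
    to a single two-sided FDR as their minimum; the direction follows the
    sign of the LFC (taken from ``neg|lfc`` or an ``lfc`` column).
    """
    df = pd.read_csv(path, sep="\t")
    gene_col = next((c for c in ("id", "gene", "Gene") if c in df.columns), None)
    if gene_col is None:
        raise ValueError("gene summary is missing required column(s): ['id']")
    _require(df, ["neg|fdr", "pos|fdr"], "gene summary")
    lfc_col = next((c for c in ("neg|lfc", "pos|lfc", "lfc") if c in df.columns),
                   None)
    if lfc_col is None:
        raise ValueError("gene summary is missing required column(s): ['neg|lfc']")
    lfc = df[lfc_col].astype(float)
    fdr = np.minimum(df["neg|fdr"].astype(float), df["pos|fdr"].astype(float))
    direction = np.where(lfc > 0, "up", np.where(lfc < 0, "down", "none"))
    return pd.DataFrame({"gene": df[gene_col], "lfc": lfc, "fdr": fdr,
                         "direction": direction})


def write_results(df: pd.DataFrame, path) -> None:
    """Write a results table as TSV (lists joined with commas)."""
    out = df.copy()
    for c in out.columns:
        if out[c].map(lambda v: isinstance(v, (list, tuple))).any():
            out[c] = out[c].map(lambda v: ",".join(map(str, v)))
    out.to_csv(path, sep="\t", index=False)
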