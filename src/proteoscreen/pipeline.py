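"""Configuration-driven pipeline tying the stages together.

A single YAML/dict configuration selects stages (screen simulation, gene
enrichment, hit calling, GSEA, lipidome simulation, lipid-class
association), carries every seed and numeric parameter, and produces a
directory of TSV outputs plus a machine-readable ``summary.json``.  Outputs
are deterministic for a fixed config: every file carries the config hash
and reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import yaml

from . import io, lipids, scoring, screen, simulate

log = logging.getLogger("proteoscreen")

DEFAULT_STAGES = ["simulate-screen", "screen-stats", "call-hits", "score",
                  "gsea", "simulate-lipidome", "lipid-corr"]


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def _write_tsv(df, path: Path, chash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: dict, out_dir=None) -> Path:
    """Execute the configured stages; returns the output directory.

    Any stage failure raises with the stage name and cause.  The summary
    JSON records seeds, parameters, the config hash, and headline numbers
    of each executed stage.
    """
    out = Path(out_dir or config.get("out_dir", "proteoscreen_run"))
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    stages = config.get("stages", DEFAULT_STAGES)
    seed = int(config.get("seed", 0))
    summary: dict = {"config_hash": chash, "seed": seed, "stages": stages,
                     "outputs": {}, "results": {}}

    state: dict = {}
    for stage in stages:
        log.info("stage %s", stage)
        try:
            _run_stage(stage, config, seed, out, chash, state, summary)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n")
    (out / "run.log").write_text(
        f"config_hash={chash}\nconfig={json.dumps(config, sort_keys=True, default=str)}\n")
    return out


def _run_stage(stage: str, config: dict, seed: int, out: Path, chash: str,
               state: dict, summary: dict) -> None:
    if stage == "simulate-screen":
        params = simulate.ScreenSimParams(**{**config.get("screen_sim", {}),
                                             "seed": seed})
        counts, truth = simulate.simulate_screen(params)
        state["counts"], state["screen_truth"] = counts, truth
        _write_tsv(counts, out / "counts.tsv", chash)
        _write_tsv(truth.gene_effects, out / "screen_truth.tsv", chash)
        summary["outputs"]["counts"] = "counts.tsv"
        summary["results"]["n_guides"] = int(len(counts))

    elif stage == "screen-stats":
        opts = config.get("screen", {})
        if "counts" not in state:
            state["counts"] = io.read_counts(opts["counts"])
        model = screen.SortedBinScreen(
            state["counts"], pseudocount=opts.get("pseudocount", 0.5))
        res = model.fit(n_perm=int(opts.get("n_perm", 10_000)), seed=seed)
        state["screen_results"] = res
        _write_tsv(res.gene_stats, out / "gene_stats.tsv", chash)
        summary["outputs"]["gene_stats"] = "gene_stats.tsv"
        summary["results"]["n_genes"] = int(len(res.gene_stats))

    elif stage == "call-hits":
        opts = config.get("hits", {})
        res = state["screen_results"]
        labels = res.call_hits(alpha=float(opts.get("alpha", 0.05)),
                               rule=opts.get("rule", "fdr"))
        hits = res.gene_stats.assign(hit=labels.to_numpy())
        state["hits"] = hits
        _write_tsv(hits, out / "hits.tsv", chash)
        summary["outputs"]["hits"] = "hits.tsv"
        summary["results"]["hits_up"] = int((labels == "up").sum())
        summary["results"]["hits_down"] = int((labels == "down").sum())

    elif stage == "score":
        opts = config.get("score", {})
        res = state["screen_results"]
        scores = res.prerank_scores(fdr_floor=opts.get("fdr_floor"))
        state["scores"] = scores
        _write_tsv(scores, out / "prerank_scores.tsv", chash)
        summary["outputs"]["prerank_scores"] = "prerank_scores.tsv"

    elif stage == "gsea":
        opts = config.get("gsea", {})
        sets = io.read_gmt(opts["gmt"]) if "gmt" in opts else state["gene_sets"]
        res = scoring.gsea_prerank(
            state["scores"], sets,
            n_perm=int(opts.get("n_perm", 1000)),
            min_size=int(opts.get("min_size", 5)),
            max_size=int(opts.get("max_size", 500)), seed=seed)
        state["gsea"] = res
        io.write_results(res, out / "gsea.tsv")
        summary["outputs"]["gsea"] = "gsea.tsv"
        summary["results"]["n_gene_sets"] = int(len(res))

    elif stage == "simulate-lipidome":
        opts = dict(config.get("lipid_sim", {}))
        if "classes" in opts:
            opts["classes"] = [simulate.LipidClassSpec(**c)
                               for c in opts["classes"]]
        params = simulate.LipidSimParams(**{**opts, "seed": seed})
        table, phenotype, truth = simulate.simulate_lipidome(params)
        state["lipid_table"], state["phenotype"] = table, phenotype
        _write_tsv(table, out / "lipid_table.tsv", chash)
        io.write_phenotype_csv(phenotype, out / "phenotype.csv")
        summary["outputs"]["lipid_table"] = "lipid_table.tsv"

    elif stage == "lipid-corr":
        opts = config.get("lipid", {})
        if "lipid_table" not in state:
            state["lipid_table"] = io.read_lipid_csv(opts["table"])
            state["phenotype"] = io.read_phenotype_csv(opts["phenotype"])
        model = lipids.LipidPhenotypeModel(
            state["lipid_table"], state["phenotype"],
            core_set=opts.get("core_set"))
        res = model.fit(inclusive_reference=opts.get("inclusive_reference", True))
        state["lipid_results"] = res
        _write_tsv(res.species_fits, out / "lipid_fits.tsv", chash)
        _write_tsv(res.class_enrichment, out / "class_enrichment.tsv", chash)
        summary["outputs"]["class_enrichment"] = "class_enrichment.tsv"
        if len(res.class_enrichment):
            best = res.class_enrichment.nsmallest(1, "p").iloc[0]
            summary["results"]["top_class"] = str(best["lipid_class"])
            summary["results"]["top_class_p"] = float(best["p"])

    else:
        raise ValueError(f"unknown stage {stage!r}")
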