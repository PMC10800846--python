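"""End-to-end pipeline orchestration.

Stages (each writes serialized artifacts into the run directory, so any stage
can be re-run from the previous stage's files):

  data -> stats -> signature -> discretize -> link -> controls

A run is driven by a :class:`RunConfig` (YAML-loadable) holding either a
synthetic-data configuration or paths to real inputs, plus every module
parameter. All stage seeds derive from one master seed via a documented
hash-based splitting rule, making the full run reproducible and each stage
reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from microsig import __version__, abundance, controls, exprlink, io, otu_stats, signature as sig, synthetic
from microsig._seeds import child_seed
from microsig.containers import ConfigError, InputError

log = logging.getLogger(__name__)

STAGES = ("data", "stats", "signature", "discretize", "link", "controls")


@dataclass
class RunConfig:
    """Everything a pipeline run needs.

    Exactly one of ``synthetic``/``inputs`` must be set. Parameter defaults
    follow the emulated study design where it states one: low-count threshold
    10, K = 6 folds, 66/34 split, 75% individual-accuracy threshold, 10
    control randomizations.
    """

    synthetic: synthetic.SimConfig | None = None
    inputs: dict | None = None  # keys: counts, metadata, tree, expression
    min_total: int = 10
    normalized_unifrac: bool = True
    n_permutations: int = 999
    # pipeline-level signature size target is 20 ("top twenty OTUs"); the
    # module-level MLConfig floor stays 5 for standalone use
    ml: sig.MLConfig = field(default_factory=lambda: sig.MLConfig(floor=20))
    stage1_tissue: str | None = "jejunum"  # None = all samples
    size_grid: tuple | None = None
    n_randomizations: int = 10
    seed: int = 0

    def validate(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ConfigError("set exactly one of synthetic / inputs")
        self.ml.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", None)
        ml = raw.pop("ml", None)
        cfg = cls(
            synthetic=synthetic.SimConfig(**syn) if syn is not None else None,
            ml=sig.MLConfig(**ml) if ml else sig.MLConfig(),
            **raw,
        )
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.blake2b(blob.encode(), digest_size=8).hexdigest()


def _stage_seed(config: RunConfig, stage: str) -> int:
    return child_seed(config.seed, stage)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_data(config: RunConfig, outdir: Path):
    """Generate or read the inputs and serialize them into the run directory."""
    outdir.mkdir(parents=True, exist_ok=True)
    if config.synthetic is not None:
        table, truth = synthetic.generate_otu_table(config.synthetic)
        tree = synthetic.generate_tree(table.otu_ids, seed=child_seed(config.synthetic.seed, "tree"))
        expr = synthetic.generate_expression(table, truth, config.synthetic)
        io.write_truth_json(truth, outdir / "truth.json")
    else:
        paths = config.inputs
        table, tree, expr = io.read_inputs(
            paths["counts"], paths["metadata"], paths.get("tree"), paths.get("expression")
        )
    io.write_counts_tsv(table, outdir / "counts.tsv")
    io.write_metadata_tsv(table, outdir / "metadata.tsv")
    if tree is not None:
        io.write_tree(tree, outdir / "tree.nwk")
    if expr is not None:
        io.write_expression_tsv(expr, outdir / "expression.tsv")
    return table, tree, expr


def load_data(outdir: Path):
    table, tree, expr = io.read_inputs(
        outdir / "counts.tsv",
        outdir / "metadata.tsv",
        outdir / "tree.nwk" if (outdir / "tree.nwk").exists() else None,
        outdir / "expression.tsv" if (outdir / "expression.tsv").exists() else None,
    )
    return table, tree, expr


def stage_stats(config: RunConfig, outdir: Path, table=None, tree=None):
    """Filtering, diversity, ordination, PERMANOVA, differential abundance."""
    if table is None:
        table, tree, _ = load_data(outdir)
    seed = _stage_seed(config, "stats")

    n_total = len(table.otu_ids)
    filtered = otu_stats.filter_low_count(table, config.min_total)
    io.write_counts_tsv(filtered, outdir / "counts_filtered.tsv")

    partition = otu_stats.presence_partition(filtered)
    alpha_line = otu_stats.observed_otus(filtered, "line")
    alpha_lt = otu_stats.observed_otus(filtered, "line_tissue")

    result = {
        "n_otus_total": n_total,
        "n_otus_filtered": len(filtered.otu_ids),
        "presence_partition": {k: sorted(v) for k, v in partition.items()},
        "alpha_observed_otus": {"line": alpha_line, "line_tissue": alpha_lt},
    }

    if tree is not None:
        dm = otu_stats.weighted_unifrac(filtered, tree, normalized=config.normalized_unifrac)
        io.write_distance_tsv(dm, outdir / "weighted_unifrac.tsv")
        pc = otu_stats.pcoa(dm, n_axes=2)
        pc.coordinates.to_csv(outdir / "pcoa_coordinates.tsv", sep="\t", float_format="%.8g")
        perm = otu_stats.permanova(dm, filtered.line_labels(), config.n_permutations, seed=seed)
        result["pcoa_explained"] = [float(x) for x in pc.explained]
        result["permanova"] = {
            "line": {
                "pseudo_F": None if np.isnan(perm.pseudo_F) else perm.pseudo_F,
                "p_value": perm.p_value,
                "n_permutations": perm.n_permutations,
            }
        }
        # line effect within each tissue
        for tissue in sorted(filtered.meta["tissue"].unique()):
            sub = filtered.subset_tissue(tissue)
            keep = sub.counts.columns[sub.counts.sum(axis=0) > 0]
            sub = sub.subset_otus(keep)
            dmt = otu_stats.weighted_unifrac(sub, tree, normalized=config.normalized_unifrac)
            pt = otu_stats.permanova(dmt, sub.line_labels(), config.n_permutations, seed=child_seed(seed, tissue))
            result["permanova"][f"line_within_{tissue}"] = {
                "pseudo_F": None if np.isnan(pt.pseudo_F) else pt.pseudo_F,
                "p_value": pt.p_value,
                "n_permutations": pt.n_permutations,
            }

    da = otu_stats.diff_abundance(filtered)
    da.to_csv(outdir / "diff_abundance.tsv", sep="\t", float_format="%.6g")
    result["diff_abundance"] = {
        "n_tested": int(da["p_value"].notna().sum()),
        "n_sig_p": int(da["sig_p"].sum()),
        "n_sig_fdr": int(da["sig_fdr"].sum()),
    }
    io.write_json(result, outdir / "stats.json")
    return result


def _stage1_table(config: RunConfig, outdir: Path):
    table, _, _ = load_data(outdir)
    filtered = otu_stats.filter_low_count(table, config.min_total)
    if config.stage1_tissue:
        filtered = filtered.subset_tissue(config.stage1_tissue)
        keep = filtered.counts.columns[filtered.counts.sum(axis=0) > 0]
        filtered = filtered.subset_otus(keep)
    return filtered


def stage_signature(config: RunConfig, outdir: Path):
    """Stage-1 search for the minimal line-predictive OTU set."""
    t1 = _stage1_table(config, outdir)
    da = pd.read_csv(outdir / "diff_abundance.tsv", sep="\t", index_col=0)
    pvals = da["p_value"].reindex(t1.otu_ids)
    seed = _stage_seed(config, "signature")
    result = sig.find_signature(t1, pvals, config.ml, seed)

    trace = [
        {"n_features": len(f), "average_accuracy": r.average_accuracy,
         "cells": {f"{c}/{v}": r.cells[(c, v)] for c, v in r.cells}}
        for f, r in result.iterations
    ]
    io.write_json(
        {
            "trace": trace,
            "best_set": result.best_set,
            "best_accuracy": result.best_accuracy,
            "final_signature": result.final_signature,
        },
        outdir / "signature.json",
    )
    pd.Series(result.per_otu, name="average_accuracy").rename_axis("otu_id").to_csv(
        outdir / "per_otu_accuracy.tsv", sep="\t", float_format="%.6g"
    )
    return result


def stage_discretize(config: RunConfig, outdir: Path):
    """Discretize each signature OTU's abundance into A/L/M/H classes."""
    t1 = _stage1_table(config, outdir)
    signature_json = json.loads((outdir / "signature.json").read_text())
    results = {}
    for otu in signature_json["final_signature"]:
        labels = abundance.discretize(t1.counts[otu], otu_id=otu)
        if labels.degenerate:
            log.warning("OTU %s discretizes to a single class; excluded from stage 2", otu)
            continue
        results[otu] = labels
    grid = abundance.class_grid(results)
    grid.rename_axis("otu_id").to_csv(outdir / "abundance_classes.tsv", sep="\t")
    io.write_json(
        {o: {"scheme": r.scheme, "thresholds": r.thresholds} for o, r in results.items()},
        outdir / "abundance_thresholds.json",
    )
    return results


def stage_link(config: RunConfig, outdir: Path):
    """Stage-2 gene-list optimization per signature OTU."""
    _, _, expr = load_data(outdir)
    if expr is None:
        raise InputError("no expression matrix available for stage 2")
    class_results = _load_classes(config, outdir)
    per_otu = pd.read_csv(outdir / "per_otu_accuracy.tsv", sep="\t", index_col=0)["average_accuracy"].to_dict()
    seed = _stage_seed(config, "link")

    results, grids = [], {}
    for otu, labels in class_results.items():
        ranked = exprlink.rank_genes(expr, labels)
        res = exprlink.optimize_gene_list(expr, labels, ranked, config.size_grid, config.ml, child_seed(seed, otu))
        results.append(res)
        grids[otu] = [{"size": s, "average_accuracy": r.average_accuracy} for s, r in res.grid]
    summary = exprlink.export_gene_lists(results, outdir / "gene_lists", line_accuracy=per_otu)
    io.write_json(grids, outdir / "gene_list_grids.json")
    return results, summary


def _load_classes(config: RunConfig, outdir: Path) -> dict[str, abundance.AbundanceClassLabels]:
    t1 = _stage1_table(config, outdir)
    grid = pd.read_csv(outdir / "abundance_classes.tsv", sep="\t", index_col=0)
    out = {}
    for otu in grid.index:
        out[otu] = abundance.discretize(t1.counts[otu], otu_id=otu)
    return out


def stage_controls(config: RunConfig, outdir: Path):
    """Label-permutation negative controls for both ML stages."""
    t1 = _stage1_table(config, outdir)
    signature_json = json.loads((outdir / "signature.json").read_text())
    seed = _stage_seed(config, "controls")

    out = {}
    best = signature_json["best_set"]
    ctl = controls.run_control(
        t1.counts[best], t1.line_labels(), config.n_randomizations, config.ml, seed
    )
    out["line"] = _control_dict(ctl)

    if (outdir / "abundance_classes.tsv").exists() and (outdir / "expression.tsv").exists():
        _, _, expr = load_data(outdir)
        class_results = _load_classes(config, outdir)
        out["abundance"] = {}
        for otu, labels in class_results.items():
            lists_dir = outdir / "gene_lists" / f"genes_{otu}.txt"
            if not lists_dir.exists():
                continue
            genes = lists_dir.read_text().split()
            X = np.log2(expr.values.loc[labels.labels.index, genes] + 1.0)
            ctl = controls.run_control(
                X, labels.labels, config.n_randomizations, config.ml,
                child_seed(seed, otu), merge_strat=True,
            )
            out["abundance"][otu] = _control_dict(ctl)
    io.write_json(out, outdir / "controls.json")
    return out


def _control_dict(ctl: controls.ControlResult) -> dict:
    return {
        "n_randomizations": ctl.n_randomizations,
        "per_run": ctl.per_run,
        "grand_mean": ctl.grand_mean,
        "chance_level": ctl.chance_level,
        "gap": ctl.gap,
        "mc_se": None if np.isnan(ctl.mc_se) else ctl.mc_se,
    }


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute every stage in order and write a manifest; returns the run dir."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for stage in STAGES:
        log.info("running stage %s", stage)
        try:
            if stage == "data":
                table, tree, expr = stage_data(config, outdir)
            elif stage == "stats":
                stage_stats(config, outdir)
            elif stage == "signature":
                stage_signature(config, outdir)
            elif stage == "discretize":
                stage_discretize(config, outdir)
            elif stage == "link":
                if (outdir / "expression.tsv").exists():
                    stage_link(config, outdir)
            elif stage == "controls":
                stage_controls(config, outdir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": {s: _stage_seed(config, s) for s in STAGES},
        "version": __version__,
    }
    io.write_json(manifest, outdir / "manifest.json")
    return outdir
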