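"""Stage-2 machine learning: gene-expression patterns predicting OTU abundance.

For each signature OTU, its discretized abundance class becomes the
classification target and the per-sample gene expression (transcripts per
million, log2(x+1)-transformed for the classifiers) becomes the attributes.
Genes are ranked by information gain alone (no differential-expression
p-value exists for a multi-class ordinal target), and the ensemble is
evaluated on nested top-k gene lists over a size grid; the best-performing
(smallest on ties) list is the OTU's gene signature.

Abundance classes can be heavily imbalanced at small n. Classes too rare to
stratify are merged into their nearest ordinal neighbor *for fold
construction only*; classifiers always see the original labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from microsig import signature as sig
from microsig.abundance import CLASS_ORDER, AbundanceClassLabels
from microsig.containers import ConfigError, ExpressionMatrix, InputError

#: sizes spanning the plausible range of optimal gene lists, plus powers of two
DEFAULT_SIZE_GRID = (32, 35, 50, 64, 83, 100, 128, 228, 256, 312, 339, 349, 500)


def merge_rare_classes(labels: pd.Series, min_count: int = 2) -> pd.Series:
    """Merge classes with fewer than ``min_count`` samples into an ordinal neighbor.

    Used for stratification only. The deficient class joins the nearest class
    (in Absent < Low < Medium < High order) that is present, ties to the
    lower class; repeats until every remaining class is large enough.
    """
    merged = labels.copy()
    order = {c: i for i, c in enumerate(CLASS_ORDER)}
    while True:
        counts = merged.value_counts()
        small = [c for c in counts.index if counts[c] < min_count]
        if not small or len(counts) < 2:
            break
        c = min(small, key=lambda x: (counts[x], order[x]))
        others = [o for o in counts.index if o != c]
        target = min(others, key=lambda o: (abs(order[o] - order[c]), order[o]))
        merged = merged.replace({c: target})
    return merged


@dataclass
class GeneListResult:
    """Grid of list sizes with ensemble performance for one OTU."""

    otu_id: str
    grid: list = field(default_factory=list)  # (size, EnsembleResult)
    best_size: int = 0
    best_gene_list: list = field(default_factory=list)
    best_average_accuracy: float = float("nan")
    degenerate: bool = False


def rank_genes(expr: ExpressionMatrix, classes: AbundanceClassLabels) -> pd.DataFrame:
    """Rank genes by information gain against the abundance classes.

    Returns a DataFrame indexed by gene id, sorted by descending gain with
    ties broken by gene id.
    """
    if classes.degenerate or classes.labels.nunique() < 2:
        raise InputError(
            f"OTU {classes.otu_id!r} has a degenerate (single-class) discretization; exclude it from stage 2"
        )
    samples = list(classes.labels.index)
    missing = sorted(set(samples) - set(expr.sample_ids))
    if missing:
        raise InputError(f"samples missing from expression matrix: {missing}")
    X = expr.values.loc[samples]
    y = classes.labels.to_numpy()
    gains = {g: sig.info_gain(X[g].to_numpy(), y) for g in X.columns}
    out = pd.DataFrame({"info_gain": pd.Series(gains)})
    out = out.loc[sorted(out.index)]
    return out.sort_values("info_gain", ascending=False, kind="mergesort")


def optimize_gene_list(
    expr: ExpressionMatrix,
    classes: AbundanceClassLabels,
    ranked: pd.DataFrame | None = None,
    size_grid=None,
    config: sig.MLConfig | None = None,
    seed: int = 0,
) -> GeneListResult:
    """Find the top-k gene list whose expression best predicts the classes."""
    config = config or sig.MLConfig()
    if ranked is None:
        ranked = rank_genes(expr, classes)
    n_genes = len(ranked)
    sizes = sorted({int(s) for s in (size_grid or DEFAULT_SIZE_GRID) if 1 <= int(s) <= n_genes})
    if not sizes:
        raise ConfigError("empty size grid after clipping to the gene count")

    samples = list(classes.labels.index)
    X = np.log2(expr.values.loc[samples] + 1.0)
    y = classes.labels
    strat = merge_rare_classes(y, min_count=2)

    grid = []
    for s in sizes:
        genes = list(ranked.index[:s])
        res = sig.evaluate_ensemble(X[genes], y.to_numpy(), config, seed, strat=strat.to_numpy())
        grid.append((s, res))
    best_size, best_res = max(grid, key=lambda g: (g[1].average_accuracy, -g[0]))
    return GeneListResult(
        otu_id=classes.otu_id,
        grid=grid,
        best_size=best_size,
        best_gene_list=list(ranked.index[:best_size]),
        best_average_accuracy=best_res.average_accuracy,
    )


def export_gene_lists(results: list[GeneListResult], outdir, line_accuracy: dict | None = None) -> pd.DataFrame:
    """Write one ranked gene list per OTU plus a summary table.

    The summary mirrors the headline per-OTU reporting: the OTU, its stage-1
    line-prediction accuracy (if supplied), its best stage-2 accuracy, and the
    optimal list size. Degenerate OTUs get a flagged row and no list file.
    """
    if not results:
        raise InputError("no gene-list results to export")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for res in results:
        row = {
            "otu_id": res.otu_id,
            "line_prediction_accuracy": (line_accuracy or {}).get(res.otu_id, np.nan),
            "best_stage2_accuracy": res.best_average_accuracy,
            "n_genes": res.best_size,
            "status": "degenerate" if res.degenerate or not res.best_gene_list else "ok",
        }
        rows.append(row)
        if row["status"] == "ok":
            path = outdir / f"genes_{res.otu_id}.txt"
            path.write_text("\n".join(res.best_gene_list) + "\n")
        else:
            warnings.warn(f"OTU {res.otu_id}: degenerate, no gene list written")
    summary = pd.DataFrame(rows)
    summary.to_csv(outdir / "gene_list_summary.tsv", sep="\t", index=False)
    return summary
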