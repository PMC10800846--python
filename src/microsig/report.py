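"""Run report: one Markdown + one JSON summary per run directory.

The report surfaces the same result shapes the analysis is organized around:
OTU totals and the low-count-filtered count, the per-line presence partition,
observed-OTU alpha summaries, PCoA coordinates, the differential-abundance
tally, the stage-1 signature trace, the abundance-class grid, the stage-2
gene-list summary, and the negative-control gaps. Partial runs render with
missing-section placeholders. The JSON report is checked against a small
structural schema shipped with the package.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from microsig.containers import InputError

#: minimal structural schema: key -> (required, type or None for any)
REPORT_SCHEMA = {
    "run_dir": (True, str),
    "stats": (False, dict),
    "signature": (False, dict),
    "classes": (False, dict),
    "stage2": (False, list),
    "controls": (False, dict),
    "missing_sections": (True, list),
}


def validate_report(obj: dict) -> None:
    """Check the JSON report's top-level structure against REPORT_SCHEMA."""
    if not isinstance(obj, dict):
        raise InputError("report must be a JSON object")
    for key, (required, typ) in REPORT_SCHEMA.items():
        if key not in obj:
            if required:
                raise InputError(f"report missing required key {key!r}")
            continue
        if typ is not None and not isinstance(obj[key], typ):
            raise InputError(f"report key {key!r} has wrong type")
    unknown = set(obj) - set(REPORT_SCHEMA)
    if unknown:
        raise InputError(f"report has unknown keys: {sorted(unknown)}")


def _load_json(path: Path):
    return json.loads(path.read_text()) if path.exists() else None


def render_report(run_dir) -> dict:
    """Assemble report.json and report.md from a run directory's artifacts."""
    run_dir = Path(run_dir)
    report: dict = {"run_dir": str(run_dir), "missing_sections": []}
    md = ["# Pipeline run report", ""]

    stats = _load_json(run_dir / "stats.json")
    if stats:
        partition_counts = {k: len(v) for k, v in stats["presence_partition"].items()}
        report["stats"] = {
            "n_otus_total": stats["n_otus_total"],
            "n_otus_filtered": stats["n_otus_filtered"],
            "presence_partition_counts": partition_counts,
            "alpha_observed_otus": stats["alpha_observed_otus"],
            "diff_abundance": stats["diff_abundance"],
            "permanova": stats.get("permanova"),
            "pcoa_explained": stats.get("pcoa_explained"),
        }
        md += [
            "## Community statistics",
            f"- OTUs: {stats['n_otus_total']} total, {stats['n_otus_filtered']} after the low-count filter",
            f"- Presence partition: {partition_counts}",
            f"- Observed OTUs per line: {stats['alpha_observed_otus']['line']}",
            f"- Differential abundance: {stats['diff_abundance']['n_sig_fdr']} OTUs at FDRp <= 0.05 "
            f"({stats['diff_abundance']['n_tested']} tested)",
            "",
        ]
    else:
        report["missing_sections"].append("stats")
        md += ["## Community statistics", "_missing_", ""]

    signature = _load_json(run_dir / "signature.json")
    if signature:
        report["signature"] = signature
        md += [
            "## Stage-1 microbial signature",
            f"- Best set: {len(signature['best_set'])} OTUs at average accuracy "
            f"{signature['best_accuracy']:.3f}",
            f"- Final signature after filters: {len(signature['final_signature'])} OTUs: "
            f"{', '.join(signature['final_signature'])}",
            "",
        ]
    else:
        report["missing_sections"].append("signature")
        md += ["## Stage-1 microbial signature", "_missing_", ""]

    classes_path = run_dir / "abundance_classes.tsv"
    if classes_path.exists():
        grid = pd.read_csv(classes_path, sep="\t", index_col=0)
        report["classes"] = {otu: grid.loc[otu].to_dict() for otu in grid.index}
        md += ["## Abundance classes (A/L/M/H)", grid.to_markdown(), ""]
    else:
        report["missing_sections"].append("classes")
        md += ["## Abundance classes", "_missing_", ""]

    summary_path = run_dir / "gene_lists" / "gene_list_summary.tsv"
    if summary_path.exists():
        summary = pd.read_csv(summary_path, sep="\t")
        report["stage2"] = summary.to_dict(orient="records")
        md += ["## Stage-2 gene lists", summary.to_markdown(index=False), ""]
    else:
        report["missing_sections"].append("stage2")
        md += ["## Stage-2 gene lists", "_missing_", ""]

    ctl = _load_json(run_dir / "controls.json")
    if ctl:
        report["controls"] = ctl
        md += ["## Negative controls"]
        line = ctl.get("line")
        if line:
            md.append(
                f"- Line task: randomized grand mean {line['grand_mean']:.3f} "
                f"(chance {line['chance_level']:.3f}, gap {line['gap']:+.3f})"
            )
        for otu, c in (ctl.get("abundance") or {}).items():
            md.append(
                f"- {otu}: randomized grand mean {c['grand_mean']:.3f} "
                f"(chance {c['chance_level']:.3f}, gap {c['gap']:+.3f})"
            )
        md.append("")
    else:
        report["missing_sections"].append("controls")
        md += ["## Negative controls", "_missing_", ""]

    validate_report(report)
    (run_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    (run_dir / "report.md").write_text("\n".join(md))
    return report
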