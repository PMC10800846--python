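"""Coupled synthetic data with planted, recoverable structure.

The generator emulates the design of a two-line chicken gut-microbiome study:
2 genetic lines (HAS/LAS) x 3 small-intestinal segments x 6 biological
replicates, an OTU count table with negative-binomial noise, a random rooted
phylogeny over the OTUs, and a transcripts-per-million expression matrix.

Planted structure, recorded in :class:`GroundTruth`:

* *discriminative OTUs* whose negative-binomial mean is multiplied by
  ``fold_change`` in one line (alternating which line is boosted);
* *line-exclusive OTUs* with a structural-zero mean in the other line, so the
  exclusivity filter downstream can be triggered deterministically;
* *linked gene modules*: for a subset of the discriminative OTUs, a block of
  genes whose log2 expression shifts by ``expr_effect_size`` per ordinal step
  of that OTU's discretized abundance class.

Everything is drawn from a single seeded generator: identical ``SimConfig``
(including seed) gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from microsig import abundance
from microsig._seeds import child_seed
from microsig.containers import ConfigError, ExpressionMatrix, InputError, OtuTable

TISSUES = ("duodenum", "jejunum", "ileum")
LINES = ("HAS", "LAS")


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated design: 2 lines x 3 tissues x 6 replicates,
    450 OTUs of which 20 are line-discriminative (4-fold mean shift) and 5 per
    line are line-exclusive, ~50k reads per sample, 2000 genes with 5 linked
    50-gene modules shifting 2 log2 units per abundance-class step.
    """

    n_tissues: int = 3
    n_replicates: int = 6
    n_otus: int = 450
    n_discriminative: int = 20
    n_exclusive_per_line: int = 5
    fold_change: float = 4.0
    nb_dispersion: float = 2.0  # NB size k; var = mu + mu^2/k
    library_size_mean: int = 50_000
    library_size_sd_log: float = 0.3
    tissue_effect_sd_log: float = 0.2
    n_genes: int = 2000
    n_linked_otus: int = 5
    n_linked_genes_per_otu: int = 50
    expr_effect_size: float = 2.0  # log2 shift per ordinal class step
    expr_noise_sd: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_tissues < 1 or self.n_tissues > len(TISSUES):
            raise ConfigError(f"n_tissues must be in 1..{len(TISSUES)}")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.n_otus < 2:
            raise ConfigError("n_otus must be >= 2")
        if self.n_discriminative + 2 * self.n_exclusive_per_line > self.n_otus:
            raise ConfigError("planted OTUs exceed n_otus")
        if self.fold_change < 1.0:
            raise ConfigError("fold_change must be >= 1")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if self.library_size_mean <= 0:
            raise ConfigError("library_size_mean must be positive")
        if self.n_linked_otus > max(self.n_discriminative, 0):
            raise ConfigError("n_linked_otus cannot exceed n_discriminative")
        if self.n_linked_otus * self.n_linked_genes_per_otu > self.n_genes:
            raise ConfigError("linked genes exceed n_genes")
        if self.expr_noise_sd <= 0:
            raise ConfigError("expr_noise_sd must be positive")

    @property
    def tissues(self) -> tuple[str, ...]:
        return TISSUES[: self.n_tissues]

    @property
    def n_samples(self) -> int:
        return 2 * self.n_tissues * self.n_replicates


@dataclass
class GroundTruth:
    """Which structure was planted, for recovery-based testing."""

    discriminative_otus: list[str] = field(default_factory=list)
    boosted_line: dict[str, str] = field(default_factory=dict)  # OTU -> line with higher mean
    exclusive_otus: dict[str, list[str]] = field(default_factory=dict)  # line -> OTUs only there
    linked_genes: dict[str, list[str]] = field(default_factory=dict)  # OTU -> gene module

    @property
    def all_exclusive(self) -> list[str]:
        return [o for otus in self.exclusive_otus.values() for o in otus]


def _otu_id(i: int) -> str:
    return f"OTU_{i + 1:04d}"


def _gene_id(i: int) -> str:
    return f"G{i + 1:05d}"


def generate_otu_table(config: SimConfig) -> tuple[OtuTable, GroundTruth]:
    """Draw the OTU count table and record the planted ground truth.

    Counts are negative binomial with per-OTU base means from a lognormal
    rank-abundance curve, a per-(OTU, tissue) lognormal main effect shared by
    both lines, a per-sample lognormal library-size factor, a ``fold_change``
    line multiplier for discriminative OTUs, and a structural-zero mean for
    exclusive OTUs in their absent line.
    """
    config.validate()
    rng = np.random.default_rng(child_seed(config.seed, "otu_table"))

    otu_ids = [_otu_id(i) for i in range(config.n_otus)]
    n_disc = config.n_discriminative
    n_excl = config.n_exclusive_per_line
    disc = otu_ids[:n_disc]
    excl_has = otu_ids[n_disc : n_disc + n_excl]
    excl_las = otu_ids[n_disc + n_excl : n_disc + 2 * n_excl]

    truth = GroundTruth(
        discriminative_otus=list(disc),
        boosted_line={o: LINES[i % 2] for i, o in enumerate(disc)},
        exclusive_otus={"HAS": list(excl_has), "LAS": list(excl_las)},
    )

    # rank-abundance: lognormal relative abundances, normalized to sum 1.
    # Discriminative OTUs emulate dominant taxa (upper half of the curve) so
    # their line effect is well covered; line-exclusive OTUs emulate rare,
    # patchily present taxa (a mean of ~1-2 reads per own-line sample), which
    # is both what real line-exclusive taxa look like and what keeps a
    # presence/absence shortcut from making them perfect predictors.
    rel = rng.lognormal(mean=0.0, sigma=1.5, size=config.n_otus)
    if n_disc:
        rel[:n_disc] = np.quantile(rel, rng.uniform(0.5, 0.95, size=n_disc))
    if n_excl:
        rel[n_disc : n_disc + 2 * n_excl] = (
            rng.uniform(0.8, 1.8, size=2 * n_excl) / config.library_size_mean * rel.sum()
        )
    rel /= rel.sum()
    tissue_fac = rng.lognormal(0.0, config.tissue_effect_sd_log, size=(config.n_tissues, config.n_otus))

    samples, rows_mu = [], []
    line_mult = np.ones((2, config.n_otus))
    for i, o in enumerate(disc):
        j = otu_ids.index(o)
        boosted = truth.boosted_line[o]
        line_mult[LINES.index(boosted), j] = config.fold_change
    for o in excl_has:
        line_mult[LINES.index("LAS"), otu_ids.index(o)] = 0.0
    for o in excl_las:
        line_mult[LINES.index("HAS"), otu_ids.index(o)] = 0.0

    meta_rows = []
    for li, line in enumerate(LINES):
        for ti, tissue in enumerate(config.tissues):
            for rep in range(1, config.n_replicates + 1):
                sid = f"{line}_{tissue}_{rep}"
                lib = config.library_size_mean * rng.lognormal(0.0, config.library_size_sd_log)
                mu = rel * tissue_fac[ti] * line_mult[li] * lib
                samples.append(sid)
                rows_mu.append(mu)
                meta_rows.append({"sample_id": sid, "line": line, "tissue": tissue, "replicate": rep})

    mu = np.vstack(rows_mu)
    k = config.nb_dispersion
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(mu > 0, k / (k + mu), 1.0)
    counts = rng.negative_binomial(k, p)
    counts[mu == 0] = 0

    counts_df = pd.DataFrame(counts, index=samples, columns=otu_ids)
    meta_df = pd.DataFrame(meta_rows).set_index("sample_id")
    return OtuTable(counts_df, meta_df), truth


def generate_tree(otu_ids, seed: int) -> TreeNode:
    """Random rooted binary tree over the OTU ids (coalescent-style joins).

    Branch lengths are exponential with a small positive floor. The leaf set
    equals ``otu_ids`` exactly; the emitted Newick is deterministic per seed.
    """
    otu_ids = list(otu_ids)
    if len(otu_ids) < 2:
        raise InputError("need at least 2 OTU ids for a tree")
    if len(set(otu_ids)) != len(otu_ids):
        raise InputError("duplicate OTU ids")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=o) for o in otu_ids]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        a.length = float(rng.exponential(0.1) + 1e-3)
        b.length = float(rng.exponential(0.1) + 1e-3)
        parent = TreeNode(children=[a, b])
        nodes = [n for idx, n in enumerate(nodes) if idx not in (int(i), int(j))]
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def generate_expression(table: OtuTable, truth: GroundTruth, config: SimConfig) -> ExpressionMatrix:
    """Draw the expression matrix with class-linked gene modules.

    For each linked OTU the generator discretizes its counts over the full
    sample set (the same rule the pipeline uses) and shifts the module's log2
    expression by ``expr_effect_size`` per ordinal class step. Columns are
    then scaled to transcripts per million (each sample sums to 1e6), which
    mildly perturbs the planted shifts the way real TPM normalization would.
    This run also freezes ``truth.linked_genes``.
    """
    config.validate()
    rng = np.random.default_rng(child_seed(config.seed, "expression"))

    gene_ids = [_gene_id(i) for i in range(config.n_genes)]
    samples = table.sample_ids
    n_s, n_g = len(samples), config.n_genes

    # choose linked OTUs among the discriminative ones; skip degenerate classes
    candidates = [o for o in truth.discriminative_otus if table.counts[o].sum() > 0]
    chosen = [str(o) for o in rng.choice(candidates, size=config.n_linked_otus, replace=False)] if config.n_linked_otus else []
    truth.linked_genes = {}
    steps = {}
    for idx, otu in enumerate(chosen):
        block = gene_ids[idx * config.n_linked_genes_per_otu : (idx + 1) * config.n_linked_genes_per_otu]
        truth.linked_genes[otu] = list(block)
        steps[otu] = abundance.discretize(table.counts[otu], otu_id=otu).ordinal_steps()

    base = rng.normal(5.0, 2.0, size=n_g)  # log2 baseline per gene
    log2 = np.tile(base, (n_s, 1)) + rng.normal(0.0, config.expr_noise_sd, size=(n_s, n_g))
    for idx, otu in enumerate(chosen):
        cols = slice(idx * config.n_linked_genes_per_otu, (idx + 1) * config.n_linked_genes_per_otu)
        shift = config.expr_effect_size * steps[otu].to_numpy(dtype=float)
        log2[:, cols] += shift[:, None]

    values = np.exp2(log2)
    values *= 1e6 / values.sum(axis=1, keepdims=True)
    df = pd.DataFrame(values, index=samples, columns=gene_ids)
    return ExpressionMatrix(df)


def generate_dataset(config: SimConfig):
    """Convenience wrapper: table, tree, expression and ground truth."""
    table, truth = generate_otu_table(config)
    tree = generate_tree(table.otu_ids, seed=child_seed(config.seed, "tree"))
    expr = generate_expression(table, truth, config)
    return table, tree, expr, truth
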