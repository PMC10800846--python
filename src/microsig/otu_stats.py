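"""Community statistics on OTU tables.

Covers the pre-ML half of the pipeline: low-count filtering, per-line
presence/absence partitioning, observed-OTU alpha diversity, weighted UniFrac
beta diversity, principal coordinates, PERMANOVA, and per-OTU
negative-binomial differential abundance with BH and Bonferroni correction.

Weighted UniFrac and PCoA are delegated to scikit-bio. PERMANOVA is computed
in-package so that it can run with an explicit seed and, on small designs,
with exhaustive enumeration of label permutations; differential abundance uses
statsmodels NB maximum likelihood with TMM effective library sizes as offsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.stats.ordination import pcoa as _skbio_pcoa
from statsmodels.stats.multitest import multipletests

from microsig.containers import ConfigError, InputError, OtuTable

GROUPINGS = ("sample", "line", "tissue", "line_tissue")


# ---------------------------------------------------------------------------
# filtering / presence
# ---------------------------------------------------------------------------

def filter_low_count(table: OtuTable, min_total: int = 10) -> OtuTable:
    """Drop OTUs whose total count across all samples is below ``min_total``.

    OTUs with fewer than ``min_total`` reads summed over every sample are
    removed; the sample set and OTU order are preserved. Idempotent.
    """
    if min_total < 0:
        raise ConfigError("min_total must be >= 0")
    totals = table.counts.sum(axis=0)
    keep = totals.index[totals >= min_total]
    if len(keep) == 0:
        raise InputError("low-count filter removed every OTU")
    return table.subset_otus(keep)


def presence_partition(table: OtuTable) -> dict[str, set]:
    """Partition observed OTUs by the line(s) they occur in.

    An OTU is present in a line iff any sample of that line has count > 0.
    Returns ``{<lineA>_only, <lineB>_only, shared}``; OTUs absent everywhere
    belong to none of the sets.
    """
    lines = table.lines
    if len(lines) != 2:
        raise InputError(f"need exactly 2 lines, found {lines}")
    present = {}
    for line in lines:
        sub = table.counts[table.meta["line"] == line]
        cols = sub.columns[(sub > 0).any(axis=0)]
        present[line] = set(cols)
    a, b = lines
    return {
        f"{a}_only": present[a] - present[b],
        f"{b}_only": present[b] - present[a],
        "shared": present[a] & present[b],
    }


def observed_otus(table: OtuTable, group_by: str = "line") -> dict:
    """Observed-OTU richness (count of OTUs with any reads) per group."""
    if group_by not in GROUPINGS:
        raise ConfigError(f"group_by must be one of {GROUPINGS}")
    if group_by == "sample":
        series = (table.counts > 0).sum(axis=1)
        return {s: int(v) for s, v in series.items()}
    if group_by == "line_tissue":
        keys = table.meta["line"].astype(str) + "/" + table.meta["tissue"].astype(str)
    else:
        keys = table.meta[group_by]
    out = {}
    for key in sorted(keys.unique()):
        sub = table.counts[keys == key]
        out[key] = int(((sub > 0).any(axis=0)).sum())
    return out


# ---------------------------------------------------------------------------
# beta diversity / ordination
# ---------------------------------------------------------------------------

def weighted_unifrac(table: OtuTable, tree: TreeNode, normalized: bool = True) -> DistanceMatrix:
    """Pairwise weighted UniFrac distances between samples.

    Raw weighted UniFrac sums, over every branch, branch length times the
    absolute difference of the two samples' relative-abundance mass descending
    through that branch; the normalized variant divides by the pair's maximum
    attainable value so distances lie in [0, 1].
    """
    leaves = {t.name for t in tree.tips()}
    missing = sorted(set(table.otu_ids) - leaves)
    if missing:
        raise InputError(f"OTUs missing from tree: {missing}")
    totals = table.counts.sum(axis=1)
    empty = sorted(totals.index[totals == 0])
    if empty:
        raise InputError(f"samples with no counts: {empty}")
    return beta_diversity(
        "weighted_unifrac",
        table.counts.to_numpy(),
        ids=table.sample_ids,
        taxa=table.otu_ids,
        tree=tree,
        normalized=normalized,
        validate=True,
    )


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # samples x retained axes
    explained: np.ndarray  # variance fraction per retained axis
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)


def pcoa(d: DistanceMatrix, n_axes: int = 2) -> PcoaResult:
    """Classical metric scaling of a distance matrix.

    Axes are ordered by decreasing eigenvalue; axes with non-positive
    eigenvalues are reported in ``eigenvalues`` but dropped from the
    coordinates.
    """
    if not isinstance(d, DistanceMatrix):
        d = DistanceMatrix(d)  # raises on asymmetry
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _skbio_pcoa(d, method="eigh")
    eig = res.eigvals.to_numpy()
    pos = eig > 1e-12 * max(eig.max(), 1.0)
    n_keep = min(n_axes, int(pos.sum()))
    coords = res.samples.iloc[:, :n_keep].copy()
    coords.index = list(d.ids)
    explained = res.proportion_explained.to_numpy()[:n_keep]
    return PcoaResult(coordinates=coords, explained=explained, eigenvalues=eig)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    exhaustive: bool = False
    degenerate: bool = False


def _permanova_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within


def _pseudo_f(d2, codes, n_groups) -> float:
    n = d2.shape[0]
    ss_total, ss_within = _permanova_ss(d2, codes, n_groups)
    ss_among = ss_total - ss_within
    if ss_within <= 0:
        return np.nan
    return (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(
    d: DistanceMatrix,
    grouping,
    n_permutations: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    The pseudo-F statistic partitions the sum of squared distances among and
    within groups; significance comes from freely permuting sample labels.
    Monte-Carlo p-values use ``(1 + #{F_perm >= F_obs}) / (1 + n_permutations)``;
    with ``exhaustive=True`` every distinct label permutation is enumerated
    and the p-value is the exact tail fraction (identity included).
    """
    labels = pd.Series(grouping)
    labels = labels.loc[list(d.ids)] if set(labels.index) >= set(d.ids) else labels
    codes, uniques = pd.factorize(labels.to_numpy())
    n_groups = len(uniques)
    if n_groups < 2:
        raise InputError("PERMANOVA needs at least 2 groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        small = [str(uniques[i]) for i in np.flatnonzero(counts < 2)]
        raise InputError(f"groups with fewer than 2 samples: {small}")

    d2 = d.data**2
    f_obs = _pseudo_f(d2, codes, n_groups)
    if np.isnan(f_obs):
        return PermanovaResult(np.nan, 1.0, 0, exhaustive, degenerate=True)

    if exhaustive:
        from sympy.utilities.iterables import multiset_permutations

        hits = total = 0
        for perm in multiset_permutations(list(codes)):
            f = _pseudo_f(d2, np.asarray(perm), n_groups)
            total += 1
            if f >= f_obs - 1e-12:
                hits += 1
        return PermanovaResult(float(f_obs), hits / total, total, exhaustive=True)

    if n_permutations < 99:
        raise ConfigError("n_permutations must be >= 99")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        f = _pseudo_f(d2, rng.permutation(codes), n_groups)
        if f >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(float(f_obs), p, n_permutations)


# ---------------------------------------------------------------------------
# differential abundance
# ---------------------------------------------------------------------------

def tmm_factors(counts: pd.DataFrame) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors per sample.

    Standard TMM: pick the sample whose upper-quartile of scaled counts is
    closest to the mean as reference; per sample, compute precision-weighted
    mean log ratio over OTUs after trimming 30% of log-ratios and 5% of
    log-abundances on each side. Factors are scaled to geometric mean 1.
    """
    y = counts.to_numpy(dtype=float).T  # OTUs x samples
    lib = y.sum(axis=0)
    if (lib == 0).any():
        raise InputError("sample with zero total count")
    uq = np.array([np.quantile(y[:, s][y[:, s] > 0], 0.75) / lib[s] if (y[:, s] > 0).any() else 0 for s in range(y.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    yr, nr = y[:, ref], lib[ref]
    factors = np.ones(y.shape[1])
    for s in range(y.shape[1]):
        if s == ref:
            continue
        ys, ns = y[:, s], lib[s]
        ok = (ys > 0) & (yr > 0)
        if ok.sum() < 2:
            continue
        m = np.log2((ys[ok] / ns) / (yr[ok] / nr))
        a = 0.5 * np.log2((ys[ok] / ns) * (yr[ok] / nr))
        w = (ns - ys[ok]) / (ns * ys[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        lo_m, hi_m = np.quantile(m, [0.3, 0.7])
        lo_a, hi_a = np.quantile(a, [0.05, 0.95])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if keep.sum() == 0 or w[keep].sum() == 0:
            continue
        factors[s] = 2 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.index, name="tmm_factor")


def _nb_lrt(y: np.ndarray, x: np.ndarray, offset: np.ndarray) -> tuple[float, float]:
    """Negative-binomial likelihood-ratio test of a binary covariate.

    Returns (log2 fold change, p-value); NaN p on irrecoverable fit failure.
    """
    import statsmodels.api as sm
    from scipy import stats

    X_full = np.column_stack([np.ones_like(x, dtype=float), x.astype(float)])
    X_null = np.ones((len(y), 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            full = sm.NegativeBinomial(y, X_full, offset=offset).fit(disp=0, maxiter=200)
            null = sm.NegativeBinomial(y, X_null, offset=offset).fit(disp=0, maxiter=200)
            llf_full, llf_null = full.llf, null.llf  # lazy; keep inside the guard
        except Exception:
            return np.nan, np.nan
    if not np.isfinite(llf_full) or not np.isfinite(llf_null):
        return np.nan, np.nan
    lr = max(2.0 * (llf_full - llf_null), 0.0)
    log2fc = full.params[1] / np.log(2)
    return float(log2fc), float(stats.chi2.sf(lr, 1))


def diff_abundance(table: OtuTable, alpha: float = 0.05) -> pd.DataFrame:
    """Per-OTU differential abundance between the two lines.

    Fits a negative-binomial GLM (log link) of counts on line with a
    log-effective-library-size offset (TMM-normalized), tests the line term by
    likelihood ratio, and adjusts p-values by Benjamini-Hochberg and
    Bonferroni over the tested OTUs. The effect estimate is the log2 fold
    change of the alphabetically first line relative to the second (HAS
    relative to LAS in the emulated design).

    OTUs with zero counts in every sample are excluded with a warning; OTUs
    whose fit fails get NaN p-values and are excluded from the corrections.
    """
    lines = table.lines
    if len(lines) != 2:
        raise InputError(f"need exactly 2 lines, found {lines}")
    for line in lines:
        if (table.meta["line"] == line).sum() < 2:
            raise InputError(f"line {line} has fewer than 2 samples")

    factors = tmm_factors(table.counts)
    offset = np.log(table.counts.sum(axis=1).to_numpy() * factors.to_numpy())
    x = (table.meta["line"] == lines[0]).to_numpy().astype(int)  # 1 = first line (HAS)

    rows = []
    for otu in table.otu_ids:
        y = table.counts[otu].to_numpy()
        if y.sum() == 0:
            warnings.warn(f"OTU {otu} has all-zero counts; excluded from testing")
            continue
        log2fc, p = _nb_lrt(y, x, offset)
        rows.append({"otu_id": otu, "log2fc": log2fc, "p_value": p})
    res = pd.DataFrame(rows).set_index("otu_id")

    tested = res["p_value"].notna()
    m = int(tested.sum())
    res["fdr_p"] = np.nan
    res["bonferroni_p"] = np.nan
    if m:
        pv = res.loc[tested, "p_value"].to_numpy()
        res.loc[tested, "fdr_p"] = multipletests(pv, method="fdr_bh")[1]
        res.loc[tested, "bonferroni_p"] = np.minimum(pv * m, 1.0)
    res["sig_p"] = res["p_value"] <= alpha
    res["sig_fdr"] = res["fdr_p"] <= alpha
    return res
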