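"""Community-statistics contracts, each checked against an independent oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from skbio import DistanceMatrix

from microsig import otu_stats as osx
from microsig.containers import ConfigError, InputError
from microsig.synthetic import generate_tree
from tests.conftest import make_table

LINES6 = ["HAS"] * 3 + ["LAS"] * 3


# ---------------------------------------------------------------------------
# filtering / presence / alpha
# ---------------------------------------------------------------------------

def test_filter_low_count_boundary_and_idempotence():
    counts = np.array([[4, 5, 60], [5, 5, 60]])
    t = make_table(counts, ["HAS", "LAS"])
    kept = osx.filter_low_count(t, 10)
    assert kept.otu_ids == ["O2", "O3"]  # totals 9, 10, 120: keep >= 10
    again = osx.filter_low_count(kept, 10)
    assert again.otu_ids == kept.otu_ids
    assert osx.filter_low_count(t, 0).otu_ids == t.otu_ids


def test_filter_matches_brute_force_sums(default_dataset):
    table = default_dataset[0]
    kept = osx.filter_low_count(table, 10)
    expected = [o for o in table.otu_ids if sum(table.counts[o]) >= 10]
    assert kept.otu_ids == expected


def test_presence_partition_semantics():
    counts = np.array(
        [[5, 0, 1, 0], [2, 0, 1, 0], [0, 3, 1, 0], [0, 1, 0, 0]]
    )
    t = make_table(counts, ["HAS", "HAS", "LAS", "LAS"])
    part = osx.presence_partition(t)
    assert part["HAS_only"] == {"O1"}
    assert part["LAS_only"] == {"O2"}
    assert part["shared"] == {"O3"}  # all-zero O4 in no set


def test_presence_partition_recovers_exclusives(default_dataset):
    table, _, _, truth = default_dataset
    part = osx.presence_partition(table)
    assert set(truth.exclusive_otus["HAS"]) <= part["HAS_only"]
    assert set(truth.exclusive_otus["LAS"]) <= part["LAS_only"]


def test_observed_otus_counts_unions(default_dataset):
    counts = np.array([[1, 1, 0, 0, 0], [0, 0, 3, 2, 0]])
    t = make_table(counts, ["HAS", "HAS"])
    assert osx.observed_otus(t, "sample") == {"S1": 2, "S2": 2}
    assert osx.observed_otus(t, "line") == {"HAS": 4}
    with pytest.raises(ConfigError):
        osx.observed_otus(t, "nope")
    # brute force on the synthetic table
    table = default_dataset[0]
    by_line = osx.observed_otus(table, "line")
    for line, n in by_line.items():
        union = (table.counts[table.meta.line == line] > 0).any(axis=0).sum()
        assert n == union


# ---------------------------------------------------------------------------
# weighted UniFrac vs a brute-force branch-enumeration oracle
# ---------------------------------------------------------------------------

def brute_force_wunifrac(tree, otu_ids, a, b, normalized):
    """Enumerate every branch explicitly; independent of scikit-bio."""
    a = np.asarray(a, float) / np.sum(a)
    b = np.asarray(b, float) / np.sum(b)
    frac = dict(zip(otu_ids, zip(a, b)))
    num = 0.0
    for node in tree.traverse(include_self=False):
        fa = sum(frac[t.name][0] for t in node.tips(include_self=True) if t.name in frac)
        fb = sum(frac[t.name][1] for t in node.tips(include_self=True) if t.name in frac)
        num += node.length * abs(fa - fb)
    if not normalized:
        return num
    den = 0.0
    for tip in tree.tips():
        if tip.name not in frac:
            continue
        depth = 0.0
        node = tip
        while not node.is_root():
            depth += node.length
            node = node.parent
        den += depth * (frac[tip.name][0] + frac[tip.name][1])
    return num / den


def test_unifrac_trivial_cases():
    tree = generate_tree(["O1", "O2"], seed=1)
    t = make_table(np.array([[10, 0], [0, 7], [5, 5]]), ["HAS", "LAS", "HAS"], otu_ids=["O1", "O2"])
    dm = osx.weighted_unifrac(t, tree, normalized=True)
    assert dm["S1", "S2"] == pytest.approx(1.0)  # disjoint mass on two leaves
    t2 = make_table(np.array([[10, 10], [3, 3]]), ["HAS", "LAS"], otu_ids=["O1", "O2"])
    dm2 = osx.weighted_unifrac(t2, tree)
    assert dm2["S1", "S2"] == pytest.approx(0.0, abs=1e-12)  # identical composition


@pytest.mark.parametrize("normalized", [True, False])
def test_unifrac_matches_brute_force(normalized):
    rng = np.random.default_rng(42)
    for rep in range(5):
        otu_ids = [f"O{i}" for i in range(12)]
        tree = generate_tree(otu_ids, seed=100 + rep)
        counts = rng.integers(0, 50, size=(8, 12))
        counts[counts.sum(axis=1) == 0, 0] = 1
        t = make_table(counts, ["HAS"] * 4 + ["LAS"] * 4, otu_ids=otu_ids)
        dm = osx.weighted_unifrac(t, tree, normalized=normalized)
        for i, j in itertools.combinations(range(8), 2):
            oracle = brute_force_wunifrac(tree, otu_ids, counts[i], counts[j], normalized)
            assert dm.data[i, j] == pytest.approx(oracle, abs=1e-10)


def test_unifrac_pseudometric_properties():
    rng = np.random.default_rng(0)
    otu_ids = [f"O{i}" for i in range(10)]
    tree = generate_tree(otu_ids, seed=3)
    counts = rng.integers(1, 40, size=(6, 10))
    t = make_table(counts, LINES6, otu_ids=otu_ids)
    d = osx.weighted_unifrac(t, tree).data
    assert np.allclose(d, d.T)
    assert np.allclose(np.diag(d), 0)
    for i, j, k in itertools.permutations(range(6), 3):
        assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


def test_unifrac_missing_otu_named():
    tree = generate_tree(["O1", "O2"], seed=1)
    t = make_table(np.array([[1, 1, 1], [1, 1, 1]]), ["HAS", "LAS"], otu_ids=["O1", "O2", "O9"])
    with pytest.raises(InputError, match="O9"):
        osx.weighted_unifrac(t, tree)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

def test_pcoa_line_geometry_recovered():
    x = np.array([0.0, 1.0, 3.0, 7.0])
    d = np.abs(x[:, None] - x[None, :])
    res = osx.pcoa(DistanceMatrix(d, ["a", "b", "c", "d"]), n_axes=3)
    assert res.explained[0] == pytest.approx(1.0, abs=1e-9)
    axis = res.coordinates.iloc[:, 0].to_numpy()
    gaps = np.abs(np.diff(axis))
    np.testing.assert_allclose(gaps, np.diff(x), atol=1e-8)


def test_pcoa_equilateral_symmetry():
    d = np.ones((3, 3)) - np.eye(3)
    res = osx.pcoa(DistanceMatrix(d, list("abc")), n_axes=3)
    eig = res.eigenvalues
    assert eig[0] == pytest.approx(eig[1], rel=1e-9)


def test_pcoa_round_trip_euclidean():
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(7, 2))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    res = osx.pcoa(DistanceMatrix(d, [f"s{i}" for i in range(7)]), n_axes=2)
    emb = res.coordinates.to_numpy()
    d2 = np.linalg.norm(emb[:, None] - emb[None, :], axis=-1)
    np.testing.assert_allclose(d, d2, atol=1e-8)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _toy_dm(seed=0, n=6):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3))
    pts[: n // 2] += 1.0
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    return DistanceMatrix(d, [f"s{i}" for i in range(n)])


def exhaustive_permanova_p(dm, labels):
    """Independent oracle: direct F formula over all label permutations."""
    d2 = dm.data**2
    n = len(labels)
    labels = np.asarray(labels)
    groups = np.unique(labels)

    def f_stat(lab):
        ss_t = d2[np.triu_indices(n, 1)].sum() / n
        ss_w = 0.0
        for g in groups:
            idx = np.flatnonzero(lab == g)
            ss_w += d2[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)].sum() / len(idx)
        return ((ss_t - ss_w) / (len(groups) - 1)) / (ss_w / (n - len(groups)))

    f_obs = f_stat(labels)
    fs = [f_stat(np.asarray(p)) for p in set(itertools.permutations(labels))]
    return sum(f >= f_obs - 1e-12 for f in fs) / len(fs)


def test_permanova_exhaustive_matches_enumeration():
    dm = _toy_dm(3)
    labels = pd.Series(["A"] * 3 + ["B"] * 3, index=list(dm.ids))
    res = osx.permanova(dm, labels, exhaustive=True)
    assert res.p_value == pytest.approx(exhaustive_permanova_p(dm, labels.to_numpy()), abs=0)
    assert res.exhaustive and res.n_permutations == 20  # C(6,3) distinct... x2 orderings


def test_permanova_agrees_with_skbio():
    from skbio.stats.distance import permanova as skbio_permanova

    dm = _toy_dm(5, n=12)
    labels = pd.Series(["A"] * 6 + ["B"] * 6, index=list(dm.ids))
    ours = osx.permanova(dm, labels, n_permutations=999, seed=1)
    ref = skbio_permanova(dm, labels.to_numpy(), permutations=999)
    assert ours.pseudo_F == pytest.approx(float(ref["test statistic"]), rel=1e-9)
    assert abs(ours.p_value - float(ref["p-value"])) < 0.05


def test_permanova_invariances():
    dm = _toy_dm(7, n=8)
    labels = np.array(["A"] * 4 + ["B"] * 4)
    res1 = osx.permanova(dm, labels, 199, seed=9)
    res2 = osx.permanova(dm, np.where(labels == "A", "X", "Y"), 199, seed=9)
    assert res1.p_value == res2.p_value and res1.pseudo_F == pytest.approx(res2.pseudo_F)
    assert res1.p_value >= 1 / 200


def test_permanova_degenerate_and_errors():
    dm = DistanceMatrix(np.zeros((4, 4)), list("abcd"))
    res = osx.permanova(dm, ["A", "A", "B", "B"], 99, seed=0)
    assert res.degenerate and res.p_value == 1.0
    with pytest.raises(InputError):
        osx.permanova(_toy_dm(1), ["A"] * 5 + ["B"], 99, 0)


# ---------------------------------------------------------------------------
# differential abundance / multiple testing
# ---------------------------------------------------------------------------

def test_single_otu_corrections_collapse():
    rng = np.random.default_rng(2)
    counts = rng.poisson(30, size=(12, 1))
    t = make_table(counts, ["HAS"] * 6 + ["LAS"] * 6)
    res = osx.diff_abundance(t)
    assert res["fdr_p"].iloc[0] == pytest.approx(res["p_value"].iloc[0])
    assert res["bonferroni_p"].iloc[0] == pytest.approx(res["p_value"].iloc[0])


def test_diff_abundance_recovers_planted(default_dataset):
    table, _, _, truth = default_dataset
    filt = osx.filter_low_count(table)
    res = osx.diff_abundance(filt)
    disc = [o for o in truth.discriminative_otus if o in res.index]
    nulls = [o for o in res.index
             if o not in set(truth.discriminative_otus) | set(truth.all_exclusive)]
    assert res.loc[disc, "sig_fdr"].mean() >= 0.8
    assert res.loc[nulls, "sig_fdr"].mean() <= 0.10
    # effect sign: boosted line HAS -> positive log2fc, LAS -> negative
    for otu in disc:
        if res.loc[otu, "sig_fdr"]:
            expected = 1 if truth.boosted_line[otu] == "HAS" else -1
            assert np.sign(res.loc[otu, "log2fc"]) == expected


def test_all_zero_otu_excluded_with_warning():
    counts = np.array([[5, 0], [7, 0], [4, 0], [6, 0]])
    t = make_table(counts, ["HAS", "HAS", "LAS", "LAS"])
    with pytest.warns(UserWarning, match="all-zero"):
        res = osx.diff_abundance(t)
    assert "O2" not in res.index


def brute_force_bh(p):
    """Step-up Benjamini-Hochberg from the definition."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
def test_bh_matches_step_up_definition(pvals):
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals)
    ours = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(ours, brute_force_bh(p), atol=1e-12)
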