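"""Stage-1 signature search: information gain, ranking, ensemble, reduction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from microsig import signature as sig
from microsig.containers import InputError
from tests.conftest import make_table


# ---------------------------------------------------------------------------
# information gain / MDL binning
# ---------------------------------------------------------------------------

def test_info_gain_hand_worked_two_bin():
    """Perfectly separating cut: gain equals the full label entropy H=1 bit."""
    values = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
    labels = np.array(["a", "a", "a", "b", "b", "b"])
    assert sig.info_gain(values, labels, cuts=[6.5]) == pytest.approx(1.0)
    # 4:2 vs 0:2 split, computed by hand:
    # H(y) = 1; H(y|left) with (3a,1b) = 0.8113, right (0a,2b) = 0
    v2 = np.array([1, 2, 3, 4, 9, 10.0])
    y2 = np.array(["a", "a", "a", "b", "b", "b"])
    gain = sig.info_gain(v2, y2, cuts=[4.5])
    h_left = -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))
    assert gain == pytest.approx(1.0 - (4 / 6) * h_left)


def test_info_gain_mdl_accepts_strong_rejects_noise():
    rng = np.random.default_rng(0)
    labels = np.array(["a"] * 30 + ["b"] * 30)
    separated = np.concatenate([rng.normal(0, 1, 30), rng.normal(8, 1, 30)])
    assert sig.info_gain(separated, labels) > 0.9
    noise = rng.normal(size=60)
    assert sig.info_gain(noise, labels) == 0.0  # MDL rejects every cut
    assert sig.mdl_cut_points(separated, labels)  # at least one accepted cut


def test_info_gain_edge_cases():
    with pytest.warns(UserWarning):
        assert sig.info_gain([1, 2, 3], ["a", "a", "a"]) == 0.0
    assert sig.info_gain([5, 5, 5, 5], ["a", "a", "b", "b"]) == 0.0  # constant feature
    with pytest.raises(InputError):
        sig.info_gain([1, 2], ["a", "b", "a"])


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.floats(-1e6, 1e6), min_size=4, max_size=30))
def test_info_gain_bounded_by_entropy(values):
    labels = np.array((["a", "b"] * 15)[: len(values)])
    g = sig.info_gain(np.asarray(values), labels)
    assert 0.0 <= g <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def test_rank_features_mean_rank_and_ties():
    ig = pd.Series({"x": 0.9, "y": 0.5, "z": 0.1})
    pv = pd.Series({"x": 0.20, "y": 0.01, "z": 0.90})
    out = sig.rank_features(ig, pv)
    # x: ig-rank 1, p-rank 2 -> 1.5 ; y: 2,1 -> 1.5 ; z: 3,3 -> 3
    assert out.loc["x", "combined_rank"] == pytest.approx(1.5)
    assert out.loc["y", "combined_rank"] == pytest.approx(1.5)
    assert list(out.index) == ["x", "y", "z"]  # tie broken by id


def test_rank_features_missing_p_goes_last():
    ig = pd.Series({"a": 0.1, "b": 0.1, "c": 0.1})
    pv = pd.Series({"a": 0.5, "c": 0.001})
    with pytest.warns(UserWarning, match="without p-value"):
        out = sig.rank_features(ig, pv)
    assert list(out.index) == ["c", "a", "b"]
    assert np.isnan(out.loc["b", "p_value"])


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------

def _sep_data(n_per=12, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n_per, 3)), rng.normal(5, 1, (n_per, 3))])
    y = np.array(["HAS"] * n_per + ["LAS"] * n_per)
    return pd.DataFrame(X, columns=["f1", "f2", "f3"]), y


def test_ensemble_perfect_on_separable():
    X, y = _sep_data()
    res = sig.evaluate_ensemble(X, y, seed=1)
    assert res.average_accuracy == pytest.approx(1.0)
    assert len(res.cells) == 6
    assert set(c for c, _ in res.cells) == set(sig.CLASSIFIERS)


def test_ensemble_near_chance_on_noise():
    rng = np.random.default_rng(5)
    accs = []
    for s in range(8):
        X = pd.DataFrame(rng.normal(size=(24, 4)))
        y = np.array(["HAS", "LAS"] * 12)
        accs.append(sig.evaluate_ensemble(X, y, seed=s).average_accuracy)
    assert abs(np.mean(accs) - 0.5) < 0.12


def test_ensemble_deterministic_and_shared_splits():
    X, y = _sep_data(seed=3)
    r1 = sig.evaluate_ensemble(X, y, seed=7)
    r2 = sig.evaluate_ensemble(X, y, seed=7)
    assert r1.cells == r2.cells


def test_ensemble_split_sizes_floor_rounding():
    y = np.array(["a"] * 6 + ["b"] * 6)
    tr, te = sig._stratified_split(y, 0.66, np.random.default_rng(0))
    # floor(0.34 * 6) = 2 test samples per class
    assert len(te) == 4 and len(tr) == 8
    assert sorted(np.unique(y[te])) == ["a", "b"]


def test_ensemble_errors():
    X = pd.DataFrame(np.ones((4, 2)))
    with pytest.raises(InputError):
        sig.evaluate_ensemble(X, ["a", "a", "a", "a"], seed=0)
    with pytest.raises(InputError):
        sig.evaluate_ensemble(X, ["a", "a", "a", "b"], seed=0)  # class of size 1


# ---------------------------------------------------------------------------
# reduction / filters
# ---------------------------------------------------------------------------

def test_reduction_keeps_informative_feature():
    rng = np.random.default_rng(2)
    y = np.array(["HAS"] * 12 + ["LAS"] * 12)
    X = pd.DataFrame(rng.normal(size=(24, 10)), columns=[f"O{i}" for i in range(10)])
    X["O0"] = np.where(y == "HAS", 5.0, -5.0) + rng.normal(0, 0.3, 24)
    gains = pd.Series({c: sig.info_gain(X[c].to_numpy(), y) for c in X.columns})
    pv = pd.Series(0.5, index=X.columns)
    pv["O0"] = 1e-9
    ranked = sig.rank_features(gains, pv)
    res = sig.reduce_dimensionality(X, y, ranked, sig.MLConfig(floor=1), seed=4)
    assert "O0" in res.best_set
    sizes = [len(f) for f, _ in res.iterations]
    assert sizes[0] == 10 and sizes[-1] == 1
    assert all(a > b for a, b in zip(sizes, sizes[1:]))  # strictly shrinking
    # dropped features are always the worst-ranked tail
    order = list(ranked.index)
    for feats, _ in res.iterations:
        assert list(feats) == order[: len(feats)]
    assert res.best_accuracy == pytest.approx(
        max(r.average_accuracy for _, r in res.iterations)
    )


def test_reduction_ties_prefer_smaller():
    it_big = ((("a", "b", "c"), sig.EnsembleResult({}, 0.9)))
    it_small = ((("a",), sig.EnsembleResult({}, 0.9)))
    best = max([it_big, it_small], key=lambda it: (it[1].average_accuracy, -len(it[0])))
    assert best is it_small


def test_filter_signature_worked_example():
    counts = np.array([[3, 3, 3], [4, 4, 4], [5, 5, 0], [6, 6, 0]])
    t = make_table(counts, ["HAS", "HAS", "LAS", "LAS"], otu_ids=["a", "b", "c"])
    per_otu = {"a": 0.90, "b": 0.74, "c": 0.90}
    # b fails the 0.75 threshold, c is HAS-only -> only a survives
    assert sig.filter_signature(per_otu, t, 0.75) == ["a"]
    assert sig.filter_signature({"a": 0.75}, t, 0.75) == ["a"]  # threshold inclusive
    with pytest.raises(InputError):
        sig.filter_signature({}, t)
    with pytest.warns(UserWarning, match="survived"):
        assert sig.filter_signature({"c": 0.99}, t) == []


def test_label_permutation_destroys_signal():
    """Shuffling y breaks the separable problem down to ~chance accuracy."""
    X, y = _sep_data(seed=11)
    rng = np.random.default_rng(13)
    accs = [
        sig.evaluate_ensemble(X, rng.permutation(y), seed=s).average_accuracy
        for s in range(6)
    ]
    assert np.mean(accs) < 0.75


def test_find_signature_on_planted_problem():
    rng = np.random.default_rng(17)
    y_line = ["HAS"] * 9 + ["LAS"] * 9
    base = rng.poisson(20, size=(18, 15))
    base[:9, :3] *= 6  # three planted discriminative OTUs
    t = make_table(base, y_line, otu_ids=[f"O{i:02d}" for i in range(15)])
    pv = pd.Series(0.5, index=t.otu_ids)
    pv[["O00", "O01", "O02"]] = 1e-6
    res = sig.find_signature(t, pv, sig.MLConfig(floor=3), seed=2)
    assert set(res.best_set) >= {"O00", "O01", "O02"} or len(res.best_set) == 3
    assert set(res.final_signature) <= set(res.best_set)
    assert all(res.per_otu[o] >= 0.75 for o in res.final_signature)
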