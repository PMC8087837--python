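"""Range-gate classifier tests: range fitting, greedy reduction against
an exhaustive oracle, intersection narrowing against the published
tables, selection semantics, and the filter-file round-trip."""

import io
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from colonygate import reference
from colonygate.dataset import LabeledDataset
from colonygate.errors import (
    ClassMismatchError,
    EmptyIntersectionError,
    InsufficientClassError,
    MissingFeatureError,
    UnknownFeatureError,
)
from colonygate.gates import (
    FilterSet,
    RangeFilter,
    RangeGateClassifier,
    apply_filters,
    build_filter_sets,
    filter_accuracy,
    fit_ranges,
    intersect_filters,
    read_filter_set,
    reduce_features,
    sample_training,
    write_filter_set,
)
from colonygate.particles import FEATURE_NAMES

F0, F1, F2 = FEATURE_NAMES[0], FEATURE_NAMES[1], FEATURE_NAMES[2]


def two_class_frame(rng, n=40, n_features=3, shift=0.0):
    """Two Gaussian classes along the first feature; labels 'A'/'B'."""
    names = list(FEATURE_NAMES[:n_features])
    a = rng.normal(0.0, 1.0, (n, n_features))
    b = rng.normal(0.0, 1.0, (n, n_features))
    a[:, 0] -= 5.0 - shift
    b[:, 0] += 5.0 - shift
    X = pd.DataFrame(np.vstack([a, b]), columns=names)
    y = pd.Series(["A"] * n + ["B"] * n)
    return X, y


# ---------------------------------------------------------------------------
# training-subset sampling


def test_sample_training_contract(table_dataset):
    ids = sample_training(table_dataset, reference.CRYPTOMONAS, 25, seed=4)
    assert len(ids) == len(set(ids)) == 25
    assert (table_dataset.labels.iloc[ids] == reference.CRYPTOMONAS).all()


def test_sample_training_deterministic(table_dataset):
    a = sample_training(table_dataset, reference.M_SMITHII, 25, seed=9)
    b = sample_training(table_dataset, reference.M_SMITHII, 25, seed=9)
    assert np.array_equal(a, b)


def test_sample_training_insufficient_class(table_dataset):
    small = table_dataset.subset(np.arange(30))  # 30 particles of one class
    with pytest.raises(InsufficientClassError):
        sample_training(small, small.labels.iloc[0], 50, seed=0)


# ---------------------------------------------------------------------------
# range fitting


def test_fit_ranges_min_max():
    X = pd.DataFrame({F0: [8.23, 9.0, 11.53]})
    filt = fit_ranges(X, "A", [F0])
    assert filt.gates == [(F0, 8.23, 11.53)]


def test_fit_ranges_degenerate_single_row():
    X = pd.DataFrame({F0: [5.0]})
    assert fit_ranges(X, "A", [F0]).gates == [(F0, 5.0, 5.0)]


def test_fit_ranges_monotone_envelope():
    X = pd.DataFrame({F0: [1.0, 4.0]})
    filt = fit_ranges(X, "A", [F0])
    X2 = pd.DataFrame({F0: [1.0, 2.5, 4.0]})  # new point inside the range
    assert fit_ranges(X2, "A", [F0]).gates == filt.gates


def test_fit_ranges_unknown_feature():
    with pytest.raises(UnknownFeatureError):
        fit_ranges(pd.DataFrame({F0: [1.0]}), "A", ["bogus"])


# ---------------------------------------------------------------------------
# greedy reduction


def exhaustive_best_subsets(filt, X, y, threshold):
    """Oracle: accuracy of every non-empty gate subset (<= 8 gates)."""
    out = {}
    for k in range(1, len(filt.gates) + 1):
        for combo in itertools.combinations(filt.gates, k):
            f = RangeFilter(filt.class_name, list(combo))
            out[tuple(g[0] for g in combo)] = filter_accuracy(f, X, y)
    return out


def test_reduction_finds_single_separating_feature():
    rng = np.random.default_rng(0)
    X, y = two_class_frame(rng, n=30, n_features=4)
    filt = fit_ranges(X[y == "A"], "A", X.columns)
    reduced = reduce_features(filt, X, y)
    assert len(reduced.gates) == 1
    assert reduced.gates[0][0] == F0
    # oracle agreement: exhaustive search also needs only one gate
    accs = exhaustive_best_subsets(filt, X, y, 0.75)
    best_single = max(v for k, v in accs.items() if len(k) == 1)
    assert best_single > 0.75


def test_reduction_result_is_minimal():
    """Removing any gate of the reduced filter drops accuracy to <= 0.75
    (the stopping rule restated)."""
    rng = np.random.default_rng(1)
    # two informative features, neither sufficient alone
    n = 60
    a = np.column_stack([rng.uniform(0, 1, n), rng.uniform(0, 1, n)])
    b = np.column_stack([rng.uniform(0.5, 1.5, n), rng.uniform(0.5, 1.5, n)])
    X = pd.DataFrame(np.vstack([a, b]), columns=[F0, F1])
    y = pd.Series(["A"] * n + ["B"] * n)
    filt = fit_ranges(X[y == "A"], "A", [F0, F1])
    reduced = reduce_features(filt, X, y)
    if len(reduced.gates) > 1:
        for i in range(len(reduced.gates)):
            rest = RangeFilter("A", reduced.gates[:i] + reduced.gates[i + 1 :])
            assert filter_accuracy(rest, X, y) <= 0.75


def test_greedy_matches_exhaustive_feasibility():
    """Whenever exhaustive search over <= 8 gates finds a subset of the
    greedy result's size with accuracy > 0.75, the greedy result itself
    clears the threshold (membership may differ)."""
    rng = np.random.default_rng(2)
    for trial in range(5):
        n, p = 40, 8
        names = list(FEATURE_NAMES[:p])
        a = rng.normal(0, 1, (n, p)) + rng.normal(0, 2, p)
        b = rng.normal(0, 1, (n, p))
        X = pd.DataFrame(np.vstack([a, b]), columns=names)
        y = pd.Series(["A"] * n + ["B"] * n)
        filt = fit_ranges(X[y == "A"], "A", names)
        reduced = reduce_features(filt, X, y)
        acc_greedy = filter_accuracy(reduced, X, y)
        accs = exhaustive_best_subsets(filt, X, y, 0.75)
        same_size = [v for k, v in accs.items() if len(k) == len(reduced.gates)]
        if any(v > 0.75 for v in same_size):
            assert acc_greedy > 0.75


def test_reduction_warns_when_already_below_threshold():
    rng = np.random.default_rng(3)
    X, y = two_class_frame(rng, n=30, n_features=1, shift=5.0)  # full overlap
    filt = fit_ranges(X[y == "A"], "A", [F0])
    if filter_accuracy(filt, X, y) <= 0.75:
        with pytest.warns(UserWarning, match="unchanged"):
            out = reduce_features(filt, X, y)
        assert out.gates == filt.gates


# ---------------------------------------------------------------------------
# intersection narrowing


def test_intersection_matches_every_published_row():
    """For every class/feature row of both published panels, the
    narrowed gate equals [max(min25, min50), min(max25, max50)] and
    reproduces the printed intersection column exactly."""
    n_rows = 0
    for row in reference.iter_gate_rows():
        (_, cls, feat, lo25, hi25, lo50, hi50, lo_int, hi_int) = row
        f25 = RangeFilter(cls, [(feat, lo25, hi25)], "25")
        f50 = RangeFilter(cls, [(feat, lo50, hi50)], "50")
        inter = intersect_filters(f25, f50)
        assert inter.gates == [(feat, max(lo25, lo50), min(hi25, hi50))]
        assert inter.gates == [(feat, lo_int, hi_int)]
        n_rows += 1
    assert n_rows == 25  # 5 + 20 published rows


def test_intersection_idempotent():
    f = RangeFilter("A", [(F0, 1.0, 2.0), (F1, 3.0, 4.0)], "25")
    inter = intersect_filters(f, f)
    assert inter.gates == f.gates
    assert inter.provenance == "intersection"


def test_intersection_carries_one_sided_features():
    f25 = RangeFilter("A", [(F0, 1.0, 2.0), (F1, 0.0, 9.0)], "25")
    f50 = RangeFilter("A", [(F0, 1.5, 2.5)], "50")
    inter = intersect_filters(f25, f50)
    assert dict((g[0], g[1:]) for g in inter.gates) == {
        F0: (1.5, 2.0),
        F1: (0.0, 9.0),
    }


def test_intersection_errors():
    with pytest.raises(ClassMismatchError):
        intersect_filters(
            RangeFilter("A", [(F0, 0, 1)]), RangeFilter("B", [(F0, 0, 1)])
        )
    with pytest.raises(EmptyIntersectionError):
        intersect_filters(
            RangeFilter("A", [(F0, 0.0, 1.0)]), RangeFilter("A", [(F0, 2.0, 3.0)])
        )


# ---------------------------------------------------------------------------
# selection semantics


def test_selection_conjunction_semantics():
    fs = FilterSet(
        [
            RangeFilter("A", [(F0, 0.0, 1.0), (F1, 0.0, 1.0)]),
            RangeFilter("B", [(F0, 2.0, 3.0)]),
        ]
    )
    X = pd.DataFrame({F0: [0.5, 0.5, 2.5], F1: [0.5, 1.5, 9.0]})
    result = apply_filters(fs, X)
    assert result.selections["A"].tolist() == [True, False, False]
    assert result.selections["B"].tolist() == [False, False, True]


def test_inclusive_bounds():
    fs = FilterSet([RangeFilter("A", [(F0, 1.0, 2.0)])])
    X = pd.DataFrame({F0: [1.0, 2.0, 0.999, 2.001]})
    assert apply_filters(fs, X).selections["A"].tolist() == [
        True,
        True,
        False,
        False,
    ]


def test_exclusive_mode_priority_and_unclassified():
    fs = FilterSet(
        [
            RangeFilter("A", [(F0, 0.0, 2.0)]),
            RangeFilter("B", [(F0, 1.0, 3.0)]),
        ]
    )
    X = pd.DataFrame({F0: [0.5, 1.5, 2.5, 9.0]})
    res = apply_filters(fs, X, mode="exclusive", priority=["B", "A"])
    assert res.exclusive_labels.tolist() == ["A", "B", "B", "unclassified"]


def test_missing_feature_column_errors():
    fs = FilterSet([RangeFilter("A", [(F0, 0.0, 1.0)])])
    with pytest.raises(MissingFeatureError):
        apply_filters(fs, pd.DataFrame({F1: [1.0]}))


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    lo=st.floats(-5, 5),
    width=st.floats(0, 4),
    shrink_lo=st.floats(0, 1),
    shrink_hi=st.floats(0, 1),
    seed=st.integers(0, 10_000),
)
def test_narrowing_a_gate_only_shrinks_selection(lo, width, shrink_lo, shrink_hi, seed):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({F0: rng.uniform(-6, 6, 80), F1: rng.uniform(-6, 6, 80)})
    hi = lo + width
    wide = FilterSet([RangeFilter("A", [(F0, lo, hi), (F1, -3.0, 3.0)])])
    nlo = lo + shrink_lo * width
    nhi = hi - shrink_hi * width
    if nlo > nhi:
        nlo = nhi = 0.5 * (nlo + nhi)
    narrow = FilterSet([RangeFilter("A", [(F0, nlo, nhi), (F1, -3.0, 3.0)])])
    sel_wide = apply_filters(wide, X).selections["A"]
    sel_narrow = apply_filters(narrow, X).selections["A"]
    assert (sel_narrow <= sel_wide).all()


def test_intersection_selection_subset_of_parents(table_dataset):
    classes = list(reference.INTERGENERIC_CLASSES)
    panel = LabeledDataset(
        table_dataset.table[table_dataset.labels.isin(classes)].reset_index(
            drop=True
        )
    )
    sets = build_filter_sets(panel, class_names=classes, seed=1)
    sel25 = apply_filters(sets["25"], panel).selections
    sel50 = apply_filters(sets["50"], panel).selections
    sel_int = apply_filters(sets["intersection"], panel).selections
    for cls in classes:
        shared = set(sets["25"][cls].feature_names) == set(
            sets["50"][cls].feature_names
        )
        if shared:
            assert (sel_int[cls] <= sel25[cls]).all()
            assert (sel_int[cls] <= sel50[cls]).all()


def test_build_filter_sets_deterministic(table_dataset):
    a = build_filter_sets(table_dataset, seed=5)
    b = build_filter_sets(table_dataset, seed=5)
    for key in ("25", "50", "intersection"):
        for fa, fb in zip(a[key].filters, b[key].filters):
            assert fa.gates == fb.gates


# ---------------------------------------------------------------------------
# estimator interface


def test_classifier_follows_sklearn_conventions():
    rng = np.random.default_rng(4)
    X, y = two_class_frame(rng, n=50)
    clf = RangeGateClassifier(features=list(X.columns))
    cloned = clone(clf)
    assert cloned.get_params() == clf.get_params()
    clf.fit(X, y)
    assert sorted(clf.classes_) == ["A", "B"]
    assert clf.n_features_in_ == 3
    pred = clf.predict(X)
    assert set(pred) <= {"A", "B", "unclassified"}
    assert clf.score(X, y) > 0.8


def test_classifier_accepts_plain_arrays():
    rng = np.random.default_rng(6)
    X, y = two_class_frame(rng, n=30)
    clf = RangeGateClassifier(features=list(X.columns)).fit(X.to_numpy(), y)
    assert clf.predict(X.to_numpy()).shape == (60,)


def test_classifier_select_flags_match_apply_filters():
    rng = np.random.default_rng(8)
    X, y = two_class_frame(rng, n=30)
    clf = RangeGateClassifier(features=list(X.columns), reduce=False).fit(X, y)
    flags = clf.select(X)
    manual = apply_filters(clf.filter_set_, X).selections
    assert flags.equals(manual)


# ---------------------------------------------------------------------------
# filter-file round-trip


def test_filter_file_round_trip_bit_exact(table_dataset):
    sets = build_filter_sets(table_dataset, seed=2)
    buf = io.StringIO()
    write_filter_set(sets["intersection"], buf)
    text = buf.getvalue()
    reread = read_filter_set(io.StringIO(text))
    buf2 = io.StringIO()
    write_filter_set(reread, buf2)
    assert buf2.getvalue() == text
    for fa, fb in zip(sets["intersection"].filters, reread.filters):
        assert fa.class_name == fb.class_name
        assert fa.gates == fb.gates
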