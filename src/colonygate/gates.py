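"""Range-gate (filter-set) classifiers.

A class is described by a *filter*: a conjunction of inclusive
``[min, max]`` gates on particle properties.  A particle is *selected* by
the filter when every gate is satisfied.  Filters are built the way the
instrument workflow builds them:

1. per class, sample 25 or 50 training particles from a pool of at most
   150 representative particles (:func:`sample_training`);
2. gate every candidate feature at the training subset's min/max
   (:func:`fit_ranges`);
3. drop gates by greedy backward elimination while overall accuracy,
   (TN + TP) / total, stays above a threshold (0.75 by default;
   :func:`reduce_features`);
4. optionally narrow the "25" and "50" filters into their *intersection*
   filter — highest min, lowest max per feature
   (:func:`intersect_filters`).

:class:`RangeGateClassifier` wraps steps 2-3 as a scikit-learn style
estimator over a labelled feature table; :func:`build_filter_sets` runs
the whole 25/50/intersection protocol.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .dataset import CLASS_COLUMN, LabeledDataset
from .errors import (
    ClassMismatchError,
    EmptyIntersectionError,
    InsufficientClassError,
    MissingFeatureError,
    UnknownFeatureError,
)
from .particles import FEATURE_NAMES

#: Particles matching no filter in exclusive mode get this label.
UNCLASSIFIED = "unclassified"

#: Cap on the per-class training pool.
TRAINING_POOL = 150


@dataclass
class RangeFilter:
    """A per-class conjunction of inclusive [min, max] feature gates."""

    class_name: str
    gates: list[tuple[str, float, float]]
    provenance: str = "custom"  # "25", "50", "intersection", or free text

    def __post_init__(self) -> None:
        seen = set()
        for name, lo, hi in self.gates:
            if name not in FEATURE_NAMES:
                raise UnknownFeatureError(f"unknown feature {name!r}")
            if name in seen:
                raise UnknownFeatureError(f"duplicate gate on {name!r}")
            if lo > hi:
                raise EmptyIntersectionError(
                    f"{self.class_name}/{name}: min {lo} > max {hi}"
                )
            seen.add(name)

    @property
    def feature_names(self) -> list[str]:
        return [g[0] for g in self.gates]

    def select(self, features: pd.DataFrame) -> pd.Series:
        """Boolean selection flags: True iff every gate is satisfied."""
        missing = [f for f in self.feature_names if f not in features.columns]
        if missing:
            raise MissingFeatureError(
                f"feature column(s) missing: {', '.join(missing)}"
            )
        flags = pd.Series(True, index=features.index)
        for name, lo, hi in self.gates:
            col = features[name]
            flags &= (col >= lo) & (col <= hi)
        return flags


@dataclass
class FilterSet:
    """One filter per class, plus the metadata to regenerate it."""

    filters: list[RangeFilter]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [f.class_name for f in self.filters]
        if len(set(names)) != len(names):
            raise ClassMismatchError("duplicate class names in filter set")

    @property
    def class_names(self) -> list[str]:
        return [f.class_name for f in self.filters]

    def __getitem__(self, class_name: str) -> RangeFilter:
        for f in self.filters:
            if f.class_name == class_name:
                return f
        raise KeyError(class_name)


@dataclass
class ClassificationResult:
    """Per-particle selection flags (one column per class filter).

    ``selections`` has one boolean column per class; ``exclusive_labels``
    (present in exclusive mode) holds the single assigned class or
    ``"unclassified"``; ``true_labels`` is carried through when known.
    """

    selections: pd.DataFrame
    exclusive_labels: pd.Series | None = None
    true_labels: pd.Series | None = None


def sample_training(
    dataset: LabeledDataset, class_name: str, n: int, seed: int
) -> np.ndarray:
    """Positional indices of ``n`` training particles for one class.

    The class pool is capped at the first :data:`TRAINING_POOL` particles
    of the class; sampling is without replacement and deterministic given
    the seed.
    """
    positions = np.flatnonzero((dataset.labels == class_name).to_numpy())
    if len(positions) > TRAINING_POOL:
        positions = positions[:TRAINING_POOL]
    if len(positions) < n:
        raise InsufficientClassError(
            f"{class_name}: pool of {len(positions)} < requested {n}"
        )
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(positions, size=n, replace=False))


def fit_ranges(
    features: pd.DataFrame,
    class_name: str,
    feature_names=FEATURE_NAMES,
    provenance: str = "custom",
) -> RangeFilter:
    """Gate every requested feature at its min/max over the subset rows."""
    if len(features) == 0:
        raise InsufficientClassError("empty training subset")
    gates = []
    for name in feature_names:
        if name not in features.columns:
            raise UnknownFeatureError(f"unknown feature {name!r}")
        col = features[name]
        gates.append((name, float(col.min()), float(col.max())))
    return RangeFilter(class_name, gates, provenance)


def filter_accuracy(
    filt: RangeFilter, features: pd.DataFrame, labels: pd.Series
) -> float:
    """Overall one-vs-rest accuracy (TN + TP) / total of one filter."""
    selected = filt.select(features).to_numpy()
    positive = (labels == filt.class_name).to_numpy()
    tp = int(np.sum(selected & positive))
    tn = int(np.sum(~selected & ~positive))
    return (tp + tn) / len(features)


def reduce_features(
    filt: RangeFilter,
    features: pd.DataFrame,
    labels: pd.Series,
    accuracy_threshold: float = 0.75,
) -> RangeFilter:
    """Greedy backward elimination of gates under the accuracy rule.

    At each step the gate whose removal yields the highest overall
    accuracy is dropped, as long as the post-removal accuracy stays above
    ``accuracy_threshold``; the procedure stops when any further removal
    would push accuracy to the threshold or below (so the result is
    minimal in that sense).  Accuracy ties are broken by dropping the
    gate whose feature comes last in the canonical feature order, keeping
    earlier-listed features preferentially.  If the input filter is
    already at or below the threshold it is returned unchanged with a
    warning.
    """
    order = {name: i for i, name in enumerate(FEATURE_NAMES)}
    current = list(filt.gates)
    if filter_accuracy(filt, features, labels) <= accuracy_threshold:
        warnings.warn(
            f"{filt.class_name}: initial filter accuracy is already <= "
            f"{accuracy_threshold}; returning it unchanged",
            stacklevel=2,
        )
        return filt
    while len(current) > 1:
        best = None  # (accuracy, order index, candidate gates)
        for i in range(len(current)):
            candidate = current[:i] + current[i + 1 :]
            acc = filter_accuracy(
                RangeFilter(filt.class_name, candidate, filt.provenance),
                features,
                labels,
            )
            key = (acc, order[current[i][0]])
            if best is None or key > best[0]:
                best = (key, candidate)
        if best[0][0] <= accuracy_threshold:
            break
        current = best[1]
    # A single remaining gate may still be removable only by emptying the
    # filter, which would select everything; that never beats the
    # threshold on data with < threshold positives, so we stop at one.
    return RangeFilter(filt.class_name, current, filt.provenance)


def intersect_filters(f25: RangeFilter, f50: RangeFilter) -> RangeFilter:
    """Narrow two filters for the same class into their intersection.

    Per feature present in both: highest min, lowest max.  Features
    present in only one filter are carried over unchanged.  An empty
    overlap (min > max) raises :class:`EmptyIntersectionError`.
    """
    if f25.class_name != f50.class_name:
        raise ClassMismatchError(
            f"cannot intersect {f25.class_name!r} with {f50.class_name!r}"
        )
    gates50 = {g[0]: g for g in f50.gates}
    gates = []
    for name, lo, hi in f25.gates:
        if name in gates50:
            _, lo2, hi2 = gates50.pop(name)
            lo, hi = max(lo, lo2), min(hi, hi2)
            if lo > hi:
                raise EmptyIntersectionError(
                    f"{f25.class_name}/{name}: empty intersection "
                    f"[{lo}, {hi}]"
                )
        gates.append((name, lo, hi))
    gates.extend(gates50.values())
    return RangeFilter(f25.class_name, gates, "intersection")


def apply_filters(
    filter_set: FilterSet,
    dataset: LabeledDataset | pd.DataFrame,
    mode: str = "perclass",
    priority: list[str] | None = None,
) -> ClassificationResult:
    """Evaluate every class filter on a dataset.

    ``perclass`` mode reports one independent boolean column per class
    (the Table-3-style evaluation); ``exclusive`` mode additionally
    assigns each particle to the first selecting class in ``priority``
    order (default: filter-set order), or ``"unclassified"``.
    """
    if mode not in ("perclass", "exclusive"):
        raise ValueError("mode must be 'perclass' or 'exclusive'")
    if isinstance(dataset, LabeledDataset):
        features = dataset.table
        truth = (
            dataset.table[CLASS_COLUMN]
            if CLASS_COLUMN in dataset.table.columns
            else None
        )
    else:
        features = dataset
        truth = None
    selections = pd.DataFrame(
        {f.class_name: f.select(features) for f in filter_set.filters},
        index=features.index,
    )
    exclusive = None
    if mode == "exclusive":
        order = priority if priority is not None else filter_set.class_names
        unknown = set(order) - set(filter_set.class_names)
        if unknown:
            raise ClassMismatchError(f"priority lists unknown classes {unknown}")
        exclusive = pd.Series(UNCLASSIFIED, index=features.index, dtype=object)
        for name in reversed(order):
            exclusive[selections[name]] = name
    return ClassificationResult(selections, exclusive, truth)


def build_filter_sets(
    dataset: LabeledDataset,
    class_names: list[str] | None = None,
    feature_names=FEATURE_NAMES,
    seed: int = 0,
    accuracy_threshold: float = 0.75,
    reduce: bool = True,
) -> dict[str, FilterSet]:
    """Run the full 25/50/intersection protocol on a labelled dataset.

    Per class, 25 and 50 training particles are sampled from the class
    pool (without replacement, the "25" subset drawn independently of the
    "50" one, each from its own seed stream).  Ranges are fitted on the
    subsets; reduction is evaluated on the union of all classes' training
    subsets (training data only — held-out rows never influence the
    gates).  Returns ``{"25": ..., "50": ..., "intersection": ...}``;
    each ``FilterSet.metadata`` records the seed, threshold and training
    row ids, and ``"training_rows"`` holds the union of positional
    indices to exclude from test data downstream.
    """
    if class_names is None:
        class_names = dataset.classes
    table = dataset.table
    out: dict[str, FilterSet] = {}
    subsets: dict[tuple[str, int], np.ndarray] = {}
    for n in (25, 50):
        for i, cls in enumerate(class_names):
            subsets[(cls, n)] = sample_training(
                dataset, cls, n, seed=seed * 1000 + n * 10 + i
            )
    for n in (25, 50):
        rows = np.sort(np.concatenate([subsets[(c, n)] for c in class_names]))
        train = table.iloc[rows]
        filters = []
        for cls in class_names:
            sub = table.iloc[subsets[(cls, n)]]
            filt = fit_ranges(sub, cls, feature_names, provenance=str(n))
            if reduce:
                filt = reduce_features(
                    filt, train, train[CLASS_COLUMN], accuracy_threshold
                )
            filters.append(filt)
        out[str(n)] = FilterSet(
            filters,
            metadata={
                "seed": seed,
                "accuracy_threshold": accuracy_threshold,
                "n_training": n,
                "training_rows": rows.tolist(),
            },
        )
    inter = [
        intersect_filters(out["25"][cls], out["50"][cls]) for cls in class_names
    ]
    all_rows = sorted(
        set(out["25"].metadata["training_rows"])
        | set(out["50"].metadata["training_rows"])
    )
    out["intersection"] = FilterSet(
        inter,
        metadata={
            "seed": seed,
            "accuracy_threshold": accuracy_threshold,
            "n_training": "25+50",
            "training_rows": all_rows,
        },
    )
    return out


class RangeGateClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn style estimator over min/max range gates.

    ``fit(X, y)`` builds one filter per class by gating each candidate
    feature at the class's min/max over the training rows, then (when
    ``reduce=True``) greedily dropping gates while one-vs-rest accuracy
    on the training data stays above ``accuracy_threshold``.

    ``predict`` assigns each particle to the first selecting class in
    ``priority`` order (default: sorted class order) or
    ``"unclassified"``; ``select`` exposes the per-class boolean flags.

    Parameters
    ----------
    features : sequence of str, optional
        Candidate gate features (default: all ten particle properties).
    accuracy_threshold : float
        Stop-rule for gate reduction.
    reduce : bool
        Whether to run greedy backward elimination after range fitting.
    priority : sequence of str, optional
        Class order used to resolve multi-selections in ``predict``.
    """

    def __init__(
        self,
        features=None,
        accuracy_threshold: float = 0.75,
        reduce: bool = True,
        priority=None,
    ):
        self.features = features
        self.accuracy_threshold = accuracy_threshold
        self.reduce = reduce
        self.priority = priority

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X)
        names = self.features if self.features is not None else FEATURE_NAMES
        if X.shape[1] != len(names):
            raise MissingFeatureError(
                f"expected {len(names)} feature columns, got {X.shape[1]}"
            )
        return pd.DataFrame(X, columns=list(names))

    def fit(self, X, y):
        frame = self._as_frame(X)
        y = pd.Series(np.asarray(y, dtype=object), index=frame.index)
        names = list(self.features) if self.features is not None else list(
            FEATURE_NAMES
        )
        missing = [n for n in names if n not in frame.columns]
        if missing:
            raise MissingFeatureError(
                f"feature column(s) missing: {', '.join(missing)}"
            )
        self.classes_ = np.array(sorted(pd.unique(y)))
        filters = []
        for cls in self.classes_:
            filt = fit_ranges(frame.loc[y == cls], cls, names)
            if self.reduce:
                filt = reduce_features(filt, frame, y, self.accuracy_threshold)
            filters.append(filt)
        self.filter_set_ = FilterSet(
            filters,
            metadata={"accuracy_threshold": self.accuracy_threshold},
        )
        self.n_features_in_ = len(names)
        self.feature_names_in_ = np.array(names)
        return self

    def select(self, X) -> pd.DataFrame:
        """Per-class boolean selection flags for each particle."""
        check_is_fitted(self, "filter_set_")
        return apply_filters(self.filter_set_, self._as_frame(X)).selections

    def predict(self, X):
        check_is_fitted(self, "filter_set_")
        order = (
            list(self.priority)
            if self.priority is not None
            else list(self.classes_)
        )
        result = apply_filters(
            self.filter_set_, self._as_frame(X), mode="exclusive", priority=order
        )
        return result.exclusive_labels.to_numpy()

    def score(self, X, y):
        """Mean exclusive-assignment accuracy against true labels."""
        return float(np.mean(self.predict(X) == np.asarray(y, dtype=object)))


# ---------------------------------------------------------------------------
# filter-file round-trip (plain structured text)


def write_filter_set(filter_set: FilterSet, path_or_buf) -> None:
    """Serialise a filter set to the plain-text filter format.

    One block per class: a ``[class <name>]`` header, a ``provenance``
    line, then one ``gate <feature> <min> <max>`` line per gate (tab
    separated; floats via ``repr`` so the round-trip is bit-exact).
    """
    buf = io.StringIO()
    for filt in filter_set.filters:
        buf.write(f"[class {filt.class_name}]\n")
        buf.write(f"provenance\t{filt.provenance}\n")
        for name, lo, hi in filt.gates:
            buf.write(f"gate\t{name}\t{lo!r}\t{hi!r}\n")
        buf.write("\n")
    text = buf.getvalue()
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


def read_filter_set(path_or_buf) -> FilterSet:
    """Parse the plain-text filter format written by `write_filter_set`."""
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf) as fh:
            text = fh.read()
    filters = []
    cls = prov = None
    gates: list[tuple[str, float, float]] = []

    def flush():
        if cls is not None:
            filters.append(RangeFilter(cls, list(gates), prov or "custom"))

    for line in text.splitlines():
        line = line.rstrip()
        if not line:
            continue
        if line.startswith("[class ") and line.endswith("]"):
            flush()
            cls, prov = line[len("[class ") : -1], None
            gates = []
        elif line.startswith("provenance\t"):
            prov = line.split("\t", 1)[1]
        elif line.startswith("gate\t"):
            _, name, lo, hi = line.split("\t")
            gates.append((name, float(lo), float(hi)))
        else:
            raise ValueError(f"unrecognised filter-file line: {line!r}")
    flush()
    return FilterSet(filters)
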