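"""Rule representation and the macroclassifier population store.

An XCSR rule ("classifier") is an IF-THEN pair: the condition is one
interval predicate ``int_i = (c_i, s_i)`` per input variable, matching
``x`` when ``c_i - s_i <= x_i < c_i + s_i``; the action is the predicted
outcome bit.  Each rule carries the usual accuracy-based bookkeeping:
predicted payoff ``p``, prediction error ``eps``, fitness ``F``,
numerosity (identical microclassifiers folded into one macroclassifier),
experience, the GA timestamp and an action-set size estimate.

The population is stored column-wise in numpy arrays so matching all
rules against an input is a single vectorised comparison; the dataclass
view (:class:`Classifier`) is materialised on demand for inspection,
export and tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["IntervalPredicate", "Classifier", "Population", "FULL_RANGE"]

#: Covering's "don't care" predicate on the [0, 1]-normalized scale.
#: The spread carries a 1e-6 margin above 0.5 because normalization maps
#: the observed maximum to exactly 1.0 and matching is half-open at the
#: top: a bare [0, 1) interval would fail to match maximal records.
FULL_RANGE = (0.5, 0.5 + 1e-6)


@dataclass(frozen=True)
class IntervalPredicate:
    """One interval predicate (center, spread) on the normalized scale."""

    center: float
    spread: float

    def __post_init__(self) -> None:
        if self.spread < 0:
            raise ValueError("spread must be >= 0")

    @property
    def lower(self) -> float:
        return self.center - self.spread

    @property
    def upper(self) -> float:
        return self.center + self.spread

    def matches(self, x: float) -> bool:
        return self.lower <= x < self.upper


@dataclass
class Classifier:
    """A macroclassifier: condition, action and quality bookkeeping."""

    condition: list[IntervalPredicate]
    action: int
    prediction: float
    prediction_error: float
    fitness: float
    numerosity: int = 1
    experience: int = 0
    ga_timestamp: int = 0
    action_set_size_estimate: float = 1.0

    def __post_init__(self) -> None:
        if self.action not in (0, 1):
            raise ValueError("action must be 0 or 1")
        if self.numerosity < 1:
            raise ValueError("numerosity must be >= 1")

    def matches(self, x) -> bool:
        return all(p.matches(v) for p, v in zip(self.condition, x, strict=True))


class Population:
    """Array-backed multiset of macroclassifiers.

    Rows ``0..n`` are live.  Removal swaps the last live row in, so row
    indices are only stable between structural modifications; the
    training loop re-derives match sets every trial.
    """

    def __init__(self, n_features: int, capacity: int = 2048):
        self.n_features = n_features
        self._cap = capacity
        self.n = 0
        self.centers = np.zeros((capacity, n_features))
        self.spreads = np.zeros((capacity, n_features))
        self.actions = np.zeros(capacity, dtype=np.int64)
        self.prediction = np.zeros(capacity)
        self.error = np.zeros(capacity)
        self.fitness = np.zeros(capacity)
        self.numerosity = np.zeros(capacity, dtype=np.int64)
        self.experience = np.zeros(capacity, dtype=np.int64)
        self.ga_timestamp = np.zeros(capacity, dtype=np.int64)
        self.as_size = np.ones(capacity)

    # -- queries ----------------------------------------------------------

    def __len__(self) -> int:
        return self.n

    @property
    def micro_count(self) -> int:
        """Total number of microclassifiers (sum of numerosities)."""
        return int(self.numerosity[: self.n].sum())

    def match_mask(self, x: np.ndarray) -> np.ndarray:
        """Boolean mask over live rows: condition matches input ``x``."""
        c = self.centers[: self.n]
        s = self.spreads[: self.n]
        return np.all((c - s <= x) & (x < c + s), axis=1)

    def mean_fitness_per_micro(self) -> float:
        micro = self.micro_count
        return float(self.fitness[: self.n].sum() / micro) if micro else 0.0

    # -- structural modification ------------------------------------------

    def _grow(self) -> None:
        new = self._cap * 2
        for name in (
            "centers", "spreads", "actions", "prediction", "error",
            "fitness", "numerosity", "experience", "ga_timestamp", "as_size",
        ):
            arr = getattr(self, name)
            shape = (new,) + arr.shape[1:]
            bigger = np.zeros(shape, dtype=arr.dtype)
            bigger[: self._cap] = arr
            setattr(self, name, bigger)
        self._cap = new

    def find_identical(self, center, spread, action: int) -> int | None:
        """Index of a live macroclassifier with this exact (condition, action)."""
        if self.n == 0:
            return None
        same = (
            (self.actions[: self.n] == action)
            & np.all(self.centers[: self.n] == center, axis=1)
            & np.all(self.spreads[: self.n] == spread, axis=1)
        )
        hits = np.flatnonzero(same)
        return int(hits[0]) if hits.size else None

    def insert(
        self,
        center,
        spread,
        action: int,
        prediction: float,
        error: float,
        fitness: float,
        *,
        numerosity: int = 1,
        experience: int = 0,
        ga_timestamp: int = 0,
        as_size: float = 1.0,
        merge: bool = True,
    ) -> int:
        """Add a rule, folding into an identical macroclassifier if present."""
        if merge:
            twin = self.find_identical(center, spread, action)
            if twin is not None:
                self.numerosity[twin] += numerosity
                return twin
        if self.n == self._cap:
            self._grow()
        i = self.n
        self.centers[i] = center
        self.spreads[i] = spread
        self.actions[i] = action
        self.prediction[i] = prediction
        self.error[i] = error
        self.fitness[i] = fitness
        self.numerosity[i] = numerosity
        self.experience[i] = experience
        self.ga_timestamp[i] = ga_timestamp
        self.as_size[i] = as_size
        self.n += 1
        return i

    def remove(self, i: int) -> None:
        """Delete macroclassifier ``i`` (swap-with-last)."""
        last = self.n - 1
        if i != last:
            for name in (
                "centers", "spreads", "actions", "prediction", "error",
                "fitness", "numerosity", "experience", "ga_timestamp", "as_size",
            ):
                arr = getattr(self, name)
                arr[i] = arr[last]
        self.n = last

    # -- dataclass views ---------------------------------------------------

    def classifier_at(self, i: int) -> Classifier:
        if not 0 <= i < self.n:
            raise IndexError(i)
        cond = [
            IntervalPredicate(float(c), float(s))
            for c, s in zip(self.centers[i], self.spreads[i])
        ]
        return Classifier(
            condition=cond,
            action=int(self.actions[i]),
            prediction=float(self.prediction[i]),
            prediction_error=float(self.error[i]),
            fitness=float(self.fitness[i]),
            numerosity=int(self.numerosity[i]),
            experience=int(self.experience[i]),
            ga_timestamp=int(self.ga_timestamp[i]),
            action_set_size_estimate=float(self.as_size[i]),
        )

    def classifiers(self) -> list[Classifier]:
        return [self.classifier_at(i) for i in range(self.n)]

    def insert_classifier(self, cl: Classifier, merge: bool = True) -> int:
        center = np.array([p.center for p in cl.condition])
        spread = np.array([p.spread for p in cl.condition])
        return self.insert(
            center, spread, cl.action, cl.prediction, cl.prediction_error,
            cl.fitness, numerosity=cl.numerosity, experience=cl.experience,
            ga_timestamp=cl.ga_timestamp, as_size=cl.action_set_size_estimate,
            merge=merge,
        )

    @classmethod
    def from_classifiers(cls, rules: list[Classifier], n_features: int | None = None) -> "Population":
        d = n_features if n_features is not None else len(rules[0].condition)
        pop = cls(d)
        for cl in rules:
            pop.insert_classifier(cl)
        return pop
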