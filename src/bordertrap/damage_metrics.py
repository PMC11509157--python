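"""Fruit damage incidence and severity from six-class injury scoring.

Each assessed fruit is binned by its number of feeding injuries into one of
six ordered classes; each class carries a damage coefficient ``V`` so that a
per-point *severity* (mean injuries per injured fruit, on the coefficient
scale) can be computed alongside the *incidence* (percent of fruit with at
least one injury).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence


class UndefinedMetricError(ValueError):
    """A damage metric is undefined for this point (e.g. no injured fruit)."""


@dataclass(frozen=True)
class DamageClass:
    label: int
    injury_min: int
    injury_max: int
    V: float


#: Default injury-count classification: class 1 = no damage (V=0), class 2 =
#: one injury (V=1), class 3 = 2-3 (V=2.5), class 4 = 4-6 (V=5),
#: class 5 = 7-10 (V=8.5), class 6 = 11-20 (V=15.5).
DEFAULT_CLASSES = (
    DamageClass(1, 0, 0, 0.0),
    DamageClass(2, 1, 1, 1.0),
    DamageClass(3, 2, 3, 2.5),
    DamageClass(4, 4, 6, 5.0),
    DamageClass(5, 7, 10, 8.5),
    DamageClass(6, 11, 20, 15.5),
)


@dataclass(frozen=True)
class DamageClassScheme:
    """Ordered injury-count classes with their damage coefficients.

    Invariants checked at construction: ranges are disjoint, contiguous from
    0 and strictly increasing; ``V`` is nondecreasing and zero exactly for
    the no-damage class.
    """

    classes: tuple[DamageClass, ...] = DEFAULT_CLASSES

    def __post_init__(self) -> None:
        cs = self.classes
        if len(cs) < 2:
            raise ValueError("scheme needs at least an uninjured and an injured class")
        if cs[0].injury_min != 0:
            raise ValueError("injury ranges must start at 0")
        for prev, cur in zip(cs, cs[1:]):
            if cur.injury_min != prev.injury_max + 1:
                raise ValueError("injury ranges must be contiguous and disjoint")
            if cur.V < prev.V:
                raise ValueError("damage coefficients must be nondecreasing")
        for c in cs:
            if c.injury_max < c.injury_min:
                raise ValueError(f"class {c.label}: empty injury range")
            if (c.V == 0) != (c.injury_min == 0 and c.injury_max == 0):
                raise ValueError("V must be 0 iff the range is exactly {0}")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def coefficients(self) -> tuple[float, ...]:
        return tuple(c.V for c in self.classes)


DEFAULT_SCHEME = DamageClassScheme()


@dataclass
class AssessmentPoint:
    """One field observation unit: 8 trees around an inter-row position.

    ``class_counts`` holds the number of fruit per damage class (ordered as
    in the scheme); the distance/catch-index fields are filled in by the
    spatial stage.
    """

    id: str
    x: float
    y: float
    class_counts: Sequence[int]
    plot_id: str = ""
    has_traps: bool = False
    management: str = "IPM"
    variety: str = ""
    distance_to_border: float | None = None
    distance_to_nearest_trap: float | None = None
    catch_index: float | None = None
    scheme: DamageClassScheme = field(default=DEFAULT_SCHEME, repr=False)

    def __post_init__(self) -> None:
        counts = [int(c) for c in self.class_counts]
        if len(counts) != self.scheme.n_classes:
            raise ValueError(
                f"expected {self.scheme.n_classes} class counts, got {len(counts)}"
            )
        if any(c < 0 for c in counts):
            raise ValueError("class counts must be nonnegative")
        self.class_counts = counts

    @property
    def total_fruit(self) -> int:
        return sum(self.class_counts)

    @property
    def injured_fruit(self) -> int:
        return self.total_fruit - self.class_counts[0]


def assign_class(injuries: int, scheme: DamageClassScheme = DEFAULT_SCHEME) -> int:
    """Map an injury count to its class label.

    Counts above the top range clamp to the top class (a fruit with more
    injuries than the scale anticipates is still maximally damaged).
    """
    if injuries < 0:
        raise ValueError("injury count must be nonnegative")
    for c in scheme.classes:
        if c.injury_min <= injuries <= c.injury_max:
            return c.label
    return scheme.classes[-1].label


def damage_incidence(point: AssessmentPoint) -> float:
    """Percent of assessed fruit with at least one injury, in [0, 100]."""
    n = point.total_fruit
    if n == 0:
        raise UndefinedMetricError(f"point {point.id}: no assessed fruit")
    return 100.0 * (n - point.class_counts[0]) / n


def damage_severity(
    point: AssessmentPoint, scheme: DamageClassScheme | None = None
) -> float:
    """Mean damage coefficient per *injured* fruit: sum(N_i V_i) / sum_{i>=2} N_i.

    Uninjured fruit (class 1, V=0) never enter the denominator, so they do
    not dilute severity. Undefined (raises) when no fruit is injured —
    downstream tables carry it as missing, not zero.
    """
    scheme = scheme or point.scheme
    counts = point.class_counts
    injured = sum(counts[1:])
    if injured == 0:
        raise UndefinedMetricError(f"point {point.id}: no injured fruit")
    num = sum(n * c.V for n, c in zip(counts, scheme.classes))
    return num / injured
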