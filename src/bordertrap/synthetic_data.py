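"""Seeded generator of synthetic border-trapping trials.

Emulates the statistical structure of a season-long orchard trial: plots
laid side by side along a straight border, pheromone traps a few meters
outside the trap plots, assessment points on a jittered row grid inward
from the border, per-point fruit tallies in six injury classes whose
incidence decays (trap plots) or drifts weakly (control plots) with border
distance, and per-trap catch series that rise through the season with
negative binomial noise, a female-biased sex ratio and a male-biased sail
split.

One scenario + one seed -> one bit-identical trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .damage_metrics import DEFAULT_SCHEME, AssessmentPoint, DamageClassScheme, assign_class
from .spatial import BorderPolyline, TrapRecord

SEXES = ("male", "female")
PARTS = ("sail", "bin")

#: Six assessment dates through a trapping season (deployment to pre-harvest).
DEFAULT_DATES = (
    "2023-05-17", "2023-06-08", "2023-07-14",
    "2023-07-26", "2023-08-11", "2023-09-02",
)

VARIETIES = ("Gala", "Kanzi", "RosyGlow", "GrannySmith")


def _default_trap_positions() -> tuple[tuple[float, float], ...]:
    # two groups of four traps, ~45 m apart, inside the two trap plots
    xs = [30.0, 75.0, 120.0, 165.0, 430.0, 475.0, 520.0, 565.0]
    return tuple((x, -7.0) for x in xs)


@dataclass
class OrchardScenario:
    """Parameters of one synthetic trial.

    Distance decay of the per-fruit injury probability is
    ``clamp(exp(intercept + slope * d), 0, 1)`` with d the border distance
    in meters, parameterized separately for trap and control plots. Catches
    are negative binomial around a per-date mean, split by the male:female
    ratio, then assigned to sail or bin by sex-specific fractions.
    """

    border_length: float = 800.0
    depth: float = 100.0
    n_points: int = 80
    fruit_per_point_mean: float = 92.0
    trap_positions: tuple[tuple[float, float], ...] = field(
        default_factory=_default_trap_positions
    )
    trap_offset: float = 7.0
    # control: weak inward drift, overall incidence ~9.4%
    incidence_intercept_control: float = math.log(0.073)
    incidence_slope_control: float = 0.005
    # trap plots: steep decay from the border, overall incidence ~13.7%
    incidence_intercept_trap: float = math.log(0.43)
    incidence_slope_trap: float = -0.03
    severity_mean_injuries: float = 2.5
    catch_mean_by_date: tuple[float, ...] = (20.0, 35.0, 60.0, 90.0, 145.0, 170.0)
    catch_dispersion: float = 5.0
    sex_ratio_mf: float = 0.85
    male_sail_fraction: float = 0.689
    female_sail_fraction: float = 0.471
    row_spacing: float = 4.0
    n_plots: int = 4
    n_border_vertices: int = 28
    scheme: DamageClassScheme = field(default=DEFAULT_SCHEME, repr=False)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0 or self.border_length <= 0:
            raise ValueError("depth and border_length must be positive")
        if self.n_points <= 0 or self.fruit_per_point_mean <= 0:
            raise ValueError("point and fruit counts must be positive")
        if any(m < 0 for m in self.catch_mean_by_date):
            raise ValueError("catch means must be nonnegative")
        if self.catch_dispersion <= 0 or self.sex_ratio_mf < 0:
            raise ValueError("dispersion must be positive, sex ratio nonnegative")
        for frac in (self.male_sail_fraction, self.female_sail_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("sail fractions must lie in [0, 1]")
        if self.severity_mean_injuries < 1.0:
            raise ValueError("mean injuries per injured fruit must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    # plots alternate trap/control from the west end, equal width
    def plot_layout(self) -> list[dict]:
        width = self.border_length / self.n_plots
        out = []
        for i in range(self.n_plots):
            out.append(
                {
                    "plot_id": f"{'T' if i % 2 == 0 else 'C'}{i // 2 + 1}",
                    "x_min": i * width,
                    "x_max": (i + 1) * width,
                    "has_traps": i % 2 == 0 and bool(self.trap_positions),
                }
            )
        return out

    def border(self) -> BorderPolyline:
        xs = np.linspace(0.0, self.border_length, self.n_border_vertices)
        return BorderPolyline(tuple((float(x), 0.0) for x in xs))

    def incidence_probability(self, distance: float, has_traps: bool) -> float:
        a, b = (
            (self.incidence_intercept_trap, self.incidence_slope_trap)
            if has_traps
            else (self.incidence_intercept_control, self.incidence_slope_control)
        )
        return float(min(1.0, math.exp(a + b * distance)))


def _ztp_lambda(mean: float) -> float:
    """Rate of the zero-truncated Poisson with the given mean (mean > 1)."""
    if mean <= 1.0:
        return 1e-9  # degenerate: almost surely one injury
    return brentq(lambda lam: lam / (1.0 - math.exp(-lam)) - mean, 1e-9, 10 * mean)


def _sample_ztp(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson draws by redrawing zeros."""
    out = rng.poisson(lam, size)
    while True:
        zeros = out == 0
        if not zeros.any():
            return out
        out[zeros] = rng.poisson(lam, int(zeros.sum()))


def generate_assessment_points(
    scenario: OrchardScenario, rng: np.random.Generator | None = None
) -> list[AssessmentPoint]:
    """Assessment points on a jittered row grid with distance-decay damage.

    Points are spread evenly over plots and row depths; per point the fruit
    total is Poisson around the scenario mean, the injured count binomial
    with the plot-stratum decay probability, and each injured fruit gets a
    zero-truncated Poisson injury count binned into classes 2..6 (counts
    above the top range clamp into the top class). Class counts always sum
    to the fruit total.
    """
    rng = scenario.rng() if rng is None else rng
    plots = scenario.plot_layout()
    # management and variety vary by parcel strip (two per plot), mirroring
    # orchards whose parcels cut across the trial plots
    management: dict[tuple[str, int], str] = {}
    variety: dict[tuple[str, int], str] = {}
    for p in plots:
        for half in (0, 1):
            management[(p["plot_id"], half)] = "organic" if rng.random() < 0.5 else "IPM"
            variety[(p["plot_id"], half)] = VARIETIES[int(rng.integers(len(VARIETIES)))]
    rows = np.arange(scenario.row_spacing / 2, scenario.depth, scenario.row_spacing)
    lam = _ztp_lambda(scenario.severity_mean_injuries)

    points: list[AssessmentPoint] = []
    for k in range(scenario.n_points):
        plot = plots[k % len(plots)]
        row_y = rows[(k // len(plots)) % len(rows)]
        x = float(rng.uniform(plot["x_min"] + 2, plot["x_max"] - 2))
        y = float(row_y + rng.uniform(-1.0, 1.0))
        y = min(max(y, 0.1), scenario.depth)
        half = int(x >= (plot["x_min"] + plot["x_max"]) / 2)
        total = max(1, int(rng.poisson(scenario.fruit_per_point_mean)))
        p_inj = scenario.incidence_probability(y, plot["has_traps"])
        injured = int(rng.binomial(total, p_inj))
        counts = [0] * scenario.scheme.n_classes
        counts[0] = total - injured
        if injured:
            for inj in _sample_ztp(rng, lam, injured):
                counts[assign_class(int(inj), scenario.scheme) - 1] += 1
        points.append(
            AssessmentPoint(
                id=f"P{k:03d}",
                x=x,
                y=y,
                class_counts=counts,
                plot_id=plot["plot_id"],
                has_traps=plot["has_traps"],
                management=management[(plot["plot_id"], half)],
                variety=variety[(plot["plot_id"], half)],
                scheme=scenario.scheme,
            )
        )
    return points


def generate_trap_catches(
    scenario: OrchardScenario,
    dates: tuple[str, ...] = DEFAULT_DATES,
    rng: np.random.Generator | None = None,
) -> list[TrapRecord]:
    """Per trap x date x sex negative binomial catches, split sail/bin.

    The per-date mean is divided between the sexes by the male:female ratio
    r (male share r/(1+r)); each sex's count is an independent NB draw with
    the scenario's dispersion (size) parameter, and each caught insect goes
    to the sail with the sex-specific probability, else to the bin.
    """
    if not dates:
        raise ValueError("need at least one date")
    if not scenario.trap_positions:
        raise ValueError("need at least one trap")
    if len(dates) != len(scenario.catch_mean_by_date):
        raise ValueError(
            f"{len(dates)} dates but {len(scenario.catch_mean_by_date)} catch means"
        )
    rng = scenario.rng() if rng is None else rng
    r = scenario.sex_ratio_mf
    male_share = r / (1.0 + r)
    size = scenario.catch_dispersion
    sail_frac = {"male": scenario.male_sail_fraction,
                 "female": scenario.female_sail_fraction}

    traps: list[TrapRecord] = []
    for t, (x, y) in enumerate(scenario.trap_positions):
        catches: dict[tuple[str, str, str], int] = {}
        for date, mean in zip(dates, scenario.catch_mean_by_date):
            for sex in SEXES:
                m = mean * (male_share if sex == "male" else 1.0 - male_share)
                if m <= 0:
                    n_caught = 0
                else:
                    n_caught = int(rng.negative_binomial(size, size / (size + m)))
                on_sail = int(rng.binomial(n_caught, sail_frac[sex]))
                catches[(date, sex, "sail")] = on_sail
                catches[(date, sex, "bin")] = n_caught - on_sail
        traps.append(TrapRecord(id=f"MSB{t + 1:02d}", x=float(x), y=float(y),
                                catches=catches))
    return traps


@dataclass
class SyntheticTrial:
    scenario: OrchardScenario
    points: list[AssessmentPoint]
    traps: list[TrapRecord]
    border: BorderPolyline
    dates: tuple[str, ...]


def generate_trial(
    scenario: OrchardScenario, dates: tuple[str, ...] = DEFAULT_DATES
) -> SyntheticTrial:
    """Generate one full trial from a single seeded stream."""
    rng = scenario.rng()
    points = generate_assessment_points(scenario, rng)
    traps = (
        generate_trap_catches(scenario, dates, rng)
        if scenario.trap_positions else []
    )
    return SyntheticTrial(scenario, points, traps, scenario.border(), dates)
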