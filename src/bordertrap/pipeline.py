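"""End-to-end analysis pipeline: catch summaries, damage metrics, spatial
joins, distance-decay models and curve summaries, behind one entry point.

Stages are pure functions over a :class:`TrialBundle`; ``run_pipeline``
chains them, writes every intermediate to the output directory and returns
the report dictionary. All randomness flows from the config seed, so the
same config + seed reproduces the summary JSON byte for byte.
"""

from __future__ import annotations

import csv
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import count_models as cm
from . import damage_curves as dc
from .damage_metrics import (
    DEFAULT_SCHEME,
    AssessmentPoint,
    DamageClassScheme,
    UndefinedMetricError,
    damage_incidence,
    damage_severity,
)
from .spatial import (
    BorderPolyline,
    TrapRecord,
    border_from_geojson,
    catch_index,
    distance_matrix,
    geojson_feature_collection,
    min_distance_to_border,
)
from .synthetic_data import DEFAULT_DATES, OrchardScenario, generate_trial

logger = logging.getLogger("bordertrap")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(name)s [%(stage)s] %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


def _log(stage: str, msg: str) -> None:
    logger.info(msg, extra={"stage": stage})


@dataclass
class TrialBundle:
    """Everything one trial's analysis needs, plus provenance."""

    points: list[AssessmentPoint]
    traps: list[TrapRecord]
    border: BorderPolyline
    scheme: DamageClassScheme = field(default=DEFAULT_SCHEME)
    config: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        plots = {p.plot_id: p.has_traps for p in self.points}
        for p in self.points:
            if plots[p.plot_id] != p.has_traps:
                raise ValueError(f"plot {p.plot_id}: inconsistent has_traps flags")


# --- CSV / GeoJSON I/O -----------------------------------------------------
# points file: id,x,y,plot_id,has_traps,management,variety,n_class1..n_class6
# catches file: trap_id,x,y,date,sex,part,count

def write_points_csv(points: list[AssessmentPoint], path: str | Path) -> None:
    n_cls = points[0].scheme.n_classes if points else 6
    cols = ["id", "x", "y", "plot_id", "has_traps", "management", "variety"] + [
        f"n_class{i + 1}" for i in range(n_cls)
    ]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for p in points:
            w.writerow(
                [p.id, f"{p.x:.3f}", f"{p.y:.3f}", p.plot_id,
                 int(p.has_traps), p.management, p.variety, *p.class_counts]
            )


def read_points_csv(
    path: str | Path, scheme: DamageClassScheme = DEFAULT_SCHEME
) -> list[AssessmentPoint]:
    df = pd.read_csv(path)
    cls_cols = [c for c in df.columns if c.startswith("n_class")]
    return [
        AssessmentPoint(
            id=str(r["id"]), x=float(r["x"]), y=float(r["y"]),
            class_counts=[int(r[c]) for c in cls_cols],
            plot_id=str(r["plot_id"]), has_traps=bool(int(r["has_traps"])),
            management=str(r["management"]), variety=str(r["variety"]),
            scheme=scheme,
        )
        for _, r in df.iterrows()
    ]


def write_catches_csv(traps: list[TrapRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["trap_id", "x", "y", "date", "sex", "part", "count"])
        for t in traps:
            for (date, sex, part), count in sorted(t.catches.items()):
                w.writerow([t.id, f"{t.x:.3f}", f"{t.y:.3f}", date, sex, part, count])


def read_catches_csv(path: str | Path) -> list[TrapRecord]:
    df = pd.read_csv(path)
    traps: dict[str, TrapRecord] = {}
    for _, r in df.iterrows():
        tid = str(r["trap_id"])
        if tid not in traps:
            traps[tid] = TrapRecord(id=tid, x=float(r["x"]), y=float(r["y"]))
        traps[tid].catches[(str(r["date"]), str(r["sex"]), str(r["part"]))] = int(
            r["count"]
        )
    return list(traps.values())


# --- catch summaries -------------------------------------------------------

def summarize_catches(bundle: TrialBundle) -> dict:
    """Season catch summary: per-trap totals, sex ratio, sail/bin split.

    All mean +/- SD pairs use the n-1 (sample) SD over traps.
    """
    traps = bundle.traps
    if not traps:
        raise ValueError("no traps to summarize")
    totals = np.array([t.total_catch for t in traps], dtype=float)
    by_sex = {s: sum(t.total_by(sex=s) for t in traps) for s in ("male", "female")}
    per_trap_sex = {
        s: np.array([t.total_by(sex=s) for t in traps], dtype=float)
        for s in ("male", "female")
    }
    mean_f = per_trap_sex["female"].mean()
    sex_ratio = float(per_trap_sex["male"].mean() / mean_f) if mean_f > 0 else np.nan

    def sail_pct(sex: str) -> tuple[float, float]:
        shares = []
        for t in traps:
            n = t.total_by(sex=sex)
            if n > 0:
                shares.append(100.0 * t.total_by(sex=sex, part="sail") / n)
        a = np.array(shares)
        if a.size == 0:
            return float("nan"), float("nan")
        return float(a.mean()), float(a.std(ddof=1)) if a.size > 1 else 0.0

    dates = sorted({d for t in traps for (d, _, _) in t.catches})
    per_date = {d: int(sum(t.total_by(date=d) for t in traps)) for d in dates}
    male_sail = sail_pct("male")
    female_sail = sail_pct("female")
    return {
        "n_traps": len(traps),
        "per_trap_totals": {t.id: int(t.total_catch) for t in traps},
        "total_catch": int(totals.sum()),
        "mean_catch_per_trap": float(totals.mean()),
        "sd_catch_per_trap": float(totals.std(ddof=1)) if totals.size > 1 else 0.0,
        "total_males": int(by_sex["male"]),
        "total_females": int(by_sex["female"]),
        "sex_ratio_mf": sex_ratio,
        "male_sail_pct_mean": male_sail[0],
        "male_sail_pct_sd": male_sail[1],
        "female_sail_pct_mean": female_sail[0],
        "female_sail_pct_sd": female_sail[1],
        "per_date_totals": per_date,
    }


# --- spatial join + damage metrics ----------------------------------------

def points_table(bundle: TrialBundle, variant: str = "displayed") -> pd.DataFrame:
    """Per-point analysis table: damage metrics joined with geometry.

    Fills each point's derived fields (border distance, nearest-trap
    distance, catch index) and returns one row per assessment point.
    Severity is missing (NaN) where no fruit is injured; ``severity_round``
    is its nearest-integer version for count-model fitting.
    """
    coords = [(p.x, p.y) for p in bundle.points]
    dmat = distance_matrix(coords, bundle.traps) if bundle.traps else None
    rows = []
    for i, p in enumerate(bundle.points):
        p.distance_to_border = min_distance_to_border((p.x, p.y), bundle.border)
        if dmat is not None:
            p.distance_to_nearest_trap = float(dmat[i].min())
            p.catch_index = catch_index(i, bundle.traps, dmat, variant)
        inc = damage_incidence(p)
        try:
            sev = damage_severity(p)
        except UndefinedMetricError:
            sev = np.nan
        rows.append(
            {
                "id": p.id, "x": p.x, "y": p.y, "plot_id": p.plot_id,
                "has_traps": p.has_traps, "management": p.management,
                "variety": p.variety, "total_fruit": p.total_fruit,
                "injured": p.injured_fruit, "incidence_pct": inc,
                "severity": sev,
                "severity_round": int(round(sev)) if np.isfinite(sev) else np.nan,
                "distance_to_border": p.distance_to_border,
                "distance_to_nearest_trap": p.distance_to_nearest_trap,
                "catch_index": p.catch_index,
            }
        )
    return pd.DataFrame(rows)


# --- modelling stage -------------------------------------------------------

FULL_DAMAGE_TERMS = (
    "catch_index",
    "distance_to_nearest_trap",
    "C(variety)",
    "has_traps",
    "C(management)",
    "has_traps:C(management)",
    "distance_to_border",
    "has_traps:distance_to_border",
)


def _fit_damage_model(
    df: pd.DataFrame, response: str, offset: str | None, family: str
) -> tuple[cm.FittedCountModel, list[dict]]:
    terms = [
        t for t in FULL_DAMAGE_TERMS
        if not (t in ("catch_index", "distance_to_nearest_trap")
                and df[t].isna().any())
    ]
    if df["has_traps"].nunique() < 2:
        terms = [t for t in terms if "has_traps" not in t]
    for drop_first in ([], ["C(variety)"], ["C(variety)", "C(management)",
                                            "has_traps:C(management)"]):
        spec = cm.ModelSpec(
            family, response, tuple(t for t in terms if t not in drop_first), offset
        )
        try:
            return cm.backward_aic(spec, df)
        except (cm.RankDeficiencyError, cm.ConvergenceError) as exc:
            last = exc
            continue
    raise last


def fit_catch_model(bundle: TrialBundle) -> tuple[cm.FittedCountModel, pd.DataFrame]:
    """Negative binomial model of per-trap catches by sex, part and date.

    One row per trap x date x sex x part. Date enters as a fixed factor;
    the sex:part interaction supports the male-vs-female-in-bin contrast.
    """
    rows = [
        {"trap_id": t.id, "date": d, "sex": s, "part": p, "count": c}
        for t in bundle.traps
        for (d, s, p), c in sorted(t.catches.items())
    ]
    df = pd.DataFrame(rows)
    spec = cm.ModelSpec(
        "negative_binomial", "count",
        ("C(sex)", "C(part)", "C(sex):C(part)", "C(date)"),
    )
    return cm.fit(spec, df), df


def model_report(model: cm.FittedCountModel, gof: cm.GofResult) -> dict:
    return {
        "formula": model.spec.formula,
        "family": model.family,
        "offset": model.spec.offset,
        "coefficients": {k: float(v) for k, v in model.coefficients.items()},
        "theta": model.theta,
        "loglik": model.loglik,
        "aic": model.aic,
        "n": model.n,
        "p": model.p,
        "pearson_chi2": gof.statistic,
        "pearson_df": gof.df,
        "pearson_p": gof.pvalue,
        "dispersion_ratio": gof.dispersion,
    }


# --- curve stage -----------------------------------------------------------

def stratum_curves(
    model: cm.FittedCountModel,
    df: pd.DataFrame,
    grid: np.ndarray,
    scale: float,
    trap_offset: float = 7.0,
) -> dict[str, dc.PredictedCurve]:
    """Predicted damage curves vs border distance for each stratum.

    Along the grid, the nearest-trap distance tracks the border distance
    plus the trap offset in the trap stratum (traps sit just outside the
    border) and stays at the stratum mean in the control stratum; the other
    covariates are pinned at stratum-typical values (mean for numeric,
    mode for categorical).
    """
    out: dict[str, dc.PredictedCurve] = {}
    for stratum, flag in (("control", False), ("trap", True)):
        sub = df[df["has_traps"] == flag]
        if sub.empty:
            continue
        cov: dict[str, object] = {"has_traps": flag}
        if "catch_index" in df.columns and sub["catch_index"].notna().all():
            cov["catch_index"] = float(sub["catch_index"].mean())
        if sub["distance_to_nearest_trap"].notna().all():
            cov["distance_to_nearest_trap"] = (
                grid + trap_offset if flag
                else float(sub["distance_to_nearest_trap"].mean())
            )
        for c in ("variety", "management"):
            cov[c] = sub[c].mode().iloc[0]
        out[stratum] = dc.predict_curve(
            model, grid, cov, scale=scale,
            max_observed=float(df["distance_to_border"].max()),
        )
    return out


def curve_summary(curves: dict[str, dc.PredictedCurve]) -> dict:
    res: dict[str, object] = {}
    for stratum, curve in curves.items():
        try:
            res[f"d50_{stratum}_m"] = dc.cumulated_d50(curve)
        except dc.UndefinedCurveError:
            res[f"d50_{stratum}_m"] = None
    if "control" in curves and "trap" in curves:
        eff = dc.differential_effect(curves["control"], curves["trap"])
        res["crossover_m"] = eff.crossover
    return res


# --- orchestration ---------------------------------------------------------

def bundle_from_config(config: dict, seed: int | None = None) -> TrialBundle:
    """Build a TrialBundle either from input files or a synthetic scenario."""
    if "points_csv" in config:
        points = read_points_csv(config["points_csv"])
        traps = read_catches_csv(config["catches_csv"])
        border = border_from_geojson(config["border_geojson"])
        return TrialBundle(points, traps, border, config=dict(config), seed=seed)
    scenario_keys = set(OrchardScenario.__dataclass_fields__) - {"scheme"}
    kwargs = {k: v for k, v in config.items() if k in scenario_keys}
    if seed is not None:
        kwargs["seed"] = seed
    if "trap_positions" in kwargs:
        kwargs["trap_positions"] = tuple(map(tuple, kwargs["trap_positions"]))
    if "catch_mean_by_date" in kwargs:
        kwargs["catch_mean_by_date"] = tuple(kwargs["catch_mean_by_date"])
    scenario = OrchardScenario(**kwargs)
    trial = generate_trial(scenario, tuple(config.get("dates", DEFAULT_DATES)))
    return TrialBundle(
        trial.points, trial.traps, trial.border,
        scheme=scenario.scheme, config=dict(config), seed=scenario.seed,
    )


def run_pipeline(
    config: dict, out_dir: str | Path | None = None, seed: int | None = None
) -> dict:
    """Run all stages; write outputs when ``out_dir`` is given.

    Returns the report dict (catch summary, model reports, curve summaries,
    provenance). Stage failures are logged with the stage name and
    re-raised; the differential-effect stage is skipped with a logged
    reason when a stratum is missing.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    variant = config.get("catch_index_variant", "displayed")
    report: dict = {"provenance": {"seed": seed, "catch_index_variant": variant}}

    _log("load", "assembling trial bundle")
    bundle = bundle_from_config(config, seed=seed)

    if bundle.traps:
        _log("catches", f"summarizing {len(bundle.traps)} traps")
        report["catch_summary"] = summarize_catches(bundle)
    else:
        _log("catches", "catch stages skipped: no traps in this trial")

    _log("metrics", f"computing damage metrics for {len(bundle.points)} points")
    df = points_table(bundle, variant=variant)
    if out is not None:
        df.to_csv(out / "points_metrics.csv", index=False)
        if bundle.traps:
            write_catches_csv(bundle.traps, out / "catches.csv")

    if bundle.traps:
        _log("models", "fitting catch model (negative binomial)")
        catch_model, _catch_df = fit_catch_model(bundle)
        report["catch_model"] = model_report(catch_model, cm.pearson_gof(catch_model))

    _log("models", "fitting damage incidence model with backward AIC")
    inc_model, inc_log = _fit_damage_model(
        df, "injured", "total_fruit", config.get("incidence_family",
                                                 "negative_binomial")
    )
    report["incidence_model"] = model_report(inc_model, cm.pearson_gof(inc_model))
    report["incidence_model"]["dropped_terms"] = [e["dropped"] for e in inc_log]

    sev_df = df.dropna(subset=["severity_round"]).copy()
    sev_df["severity_round"] = sev_df["severity_round"].astype(int)
    _log("models", f"fitting damage severity model on {len(sev_df)} injured points")
    sev_model, sev_log = _fit_damage_model(
        sev_df, "severity_round", None, "negative_binomial"
    )
    report["severity_model"] = model_report(sev_model, cm.pearson_gof(sev_model))
    report["severity_model"]["dropped_terms"] = [e["dropped"] for e in sev_log]

    _log("curves", "building distance-decay curves")
    grid = dc.make_grid(float(df["distance_to_border"].max()))
    sev_grid = dc.make_grid(float(sev_df["distance_to_border"].max()))
    trap_offset = float(config.get("trap_offset", 7.0))
    inc_curves = stratum_curves(inc_model, df, grid, scale=100.0,
                                trap_offset=trap_offset)
    sev_curves = stratum_curves(sev_model, sev_df, sev_grid, scale=1.0,
                                trap_offset=trap_offset)
    report["incidence_curves"] = curve_summary(inc_curves)
    report["severity_curves"] = curve_summary(sev_curves)
    if "control" not in inc_curves or "trap" not in inc_curves:
        _log("curves", "differential-effect stage skipped: only one stratum present")

    report["incidence_by_stratum"] = {
        ("trap" if k else "control"): {
            "mean_pct": float(v.mean()),
            "sd_pct": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
        }
        for k, v in df.groupby("has_traps")["incidence_pct"]
    }
    report["severity_by_stratum"] = {
        ("trap" if k else "control"): {
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
        }
        for k, v in df.dropna(subset=["severity"]).groupby("has_traps")["severity"]
    }

    if out is not None:
        _log("write", f"writing report files to {out}")
        for name, curves in (("incidence", inc_curves), ("severity", sev_curves)):
            for stratum, c in curves.items():
                pd.DataFrame(
                    {
                        "distance_m": c.grid,
                        "prediction": c.values,
                        "se": c.se,
                        "cumulated_fraction": dc.cumulated_fraction(c),
                    }
                ).to_csv(out / f"curve_{name}_{stratum}.csv", index=False)
        (out / "summary.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
    return report


def write_synthetic_inputs(scenario: OrchardScenario, out_dir: str | Path) -> dict:
    """Materialize a synthetic trial as the pipeline's CSV/GeoJSON inputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trial = generate_trial(scenario)
    write_points_csv(trial.points, out / "points.csv")
    write_catches_csv(trial.traps, out / "catches.csv")
    (out / "border.geojson").write_text(
        json.dumps(geojson_feature_collection(trial.border, trial.traps), indent=2)
    )
    return {
        "points_csv": str(out / "points.csv"),
        "catches_csv": str(out / "catches.csv"),
        "border_geojson": str(out / "border.geojson"),
    }
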