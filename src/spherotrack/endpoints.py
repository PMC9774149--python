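"""Growth and drug-response endpoints.

Aggregates per-image morphometrics and absorbance readouts into the
study endpoints:

* RTV = V_terminal / V_original (per well, terminal day defaults to 7);
* TGI% = (RTV_control - RTV_treatment) / RTV_control * 100, computed
  against the vehicle group of the same oxygen condition;
* day-7 / day-1 equivalent-diameter ratio;
* viability normalized to the vehicle control (background-subtracted
  A570 - A600 signal);
* strict EPI < threshold invasiveness classification (default 0.5);
* four-parameter logistic dose-response fits with explicit
  "ic50-not-reached" status when no viability crosses 50%.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import (
    DegenerateControlError,
    InsufficientDataError,
    InvalidArgumentError,
)

__all__ = [
    "WellSeries",
    "TGIResult",
    "DoseResponseFit",
    "relative_tumor_volume",
    "tumor_growth_inhibition",
    "diameter_ratio",
    "normalize_viability",
    "classify_invasiveness",
    "fit_dose_response",
    "summarize_plate",
]

VEHICLE_DOSE = 0.0


@dataclass
class WellSeries:
    """Ordered per-day records for one well."""

    well_id: str
    condition: str
    dose_uM: float
    days: list[int]
    diameters_um: list[float]
    volumes_um3: list[float]
    epi: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if sorted(set(self.days)) != list(self.days):
            raise InvalidArgumentError(
                f"well {self.well_id}: days must be unique and increasing")

    def volume_on(self, day: int) -> float:
        try:
            return self.volumes_um3[self.days.index(day)]
        except ValueError:
            raise InvalidArgumentError(
                f"well {self.well_id}: no record for day {day}") from None

    def diameter_on(self, day: int) -> float:
        try:
            return self.diameters_um[self.days.index(day)]
        except ValueError:
            raise InvalidArgumentError(
                f"well {self.well_id}: no record for day {day}") from None


@dataclass(frozen=True)
class TGIResult:
    dose_uM: float
    condition: str
    RTV_control: float
    RTV_treatment: float
    TGI_percent: float
    n_control: int
    n_treatment: int


@dataclass
class DoseResponseFit:
    """4PL fit summary; ``params`` is None unless status is "ok"."""

    doses: np.ndarray
    viabilities: np.ndarray
    status: str                      # "ok" | "ic50-not-reached" | "fit-failed"
    params: dict | None = None       # bottom, top, ic50, slope
    ic50_ci: tuple[float, float] | None = None
    rmse: float | None = None
    anomalous_direction: bool = False


def relative_tumor_volume(V_terminal: float, V_original: float) -> float:
    """RTV = V_terminal / V_original."""
    for name, v in (("V_terminal", V_terminal), ("V_original", V_original)):
        if not math.isfinite(v) or v <= 0:
            raise InvalidArgumentError(f"{name} must be > 0, got {v}")
    return V_terminal / V_original


def tumor_growth_inhibition(RTV_control: float, RTV_treatment: float) -> float:
    """TGI% = (RTV_control - RTV_treatment) / RTV_control * 100.

    Negative values are allowed (treated group grew more than control).
    """
    if not math.isfinite(RTV_control) or RTV_control <= 0:
        raise InvalidArgumentError(
            f"RTV_control must be > 0, got {RTV_control}")
    if not math.isfinite(RTV_treatment) or RTV_treatment < 0:
        raise InvalidArgumentError(
            f"RTV_treatment must be >= 0, got {RTV_treatment}")
    return (RTV_control - RTV_treatment) / RTV_control * 100.0


def diameter_ratio(series: WellSeries, day_a: int = 7, day_b: int = 1) -> float:
    """d(day_a) / d(day_b); defaults to the day-7 over day-1 ratio."""
    da = series.diameter_on(day_a)
    db = series.diameter_on(day_b)
    if db <= 0:
        raise InvalidArgumentError(
            f"well {series.well_id}: non-positive diameter on day {day_b}")
    return da / db


def _signal(pairs: np.ndarray) -> np.ndarray:
    pairs = np.atleast_2d(np.asarray(pairs, dtype=float))
    if pairs.shape[1] != 2:
        raise InvalidArgumentError("absorbance pairs must be (N, 2): A570, A600")
    return pairs[:, 0] - pairs[:, 1]


def normalize_viability(sample, control, blank=None) -> tuple[float, float]:
    """Percent viability relative to control, with propagated SEM.

    Signal per well is background-subtracted ``A570 - A600``;
    viability% = 100 * mean(sample signal) / mean(control signal). The
    SEM combines sample and control replicate scatter by the delta
    method. Returns ``(viability_percent, sem_percent)``.
    """
    s = _signal(sample)
    c = _signal(control)
    if len(c) < 1:
        raise InvalidArgumentError("at least one control replicate required")
    bg = float(_signal(blank).mean()) if blank is not None and len(
        np.atleast_2d(blank)) else 0.0
    s = s - bg
    c = c - bg
    mc = float(c.mean())
    if mc <= 0:
        raise DegenerateControlError(
            f"control signal mean {mc:.4g} is not positive")
    ms = float(s.mean())
    viability = 100.0 * ms / mc
    sem_s = float(s.std(ddof=1) / np.sqrt(len(s))) if len(s) > 1 else 0.0
    sem_c = float(c.std(ddof=1) / np.sqrt(len(c))) if len(c) > 1 else 0.0
    sem = 100.0 * math.hypot(sem_s / mc, ms * sem_c / mc ** 2)
    return viability, sem


def classify_invasiveness(EPI_terminal: float, threshold: float = 0.5) -> str:
    """"less-invasive" iff EPI < threshold (strict), else "invasive"."""
    if not math.isfinite(EPI_terminal):
        raise InvalidArgumentError(f"EPI must be finite, got {EPI_terminal}")
    if not math.isfinite(threshold):
        raise InvalidArgumentError("threshold must be finite")
    return "less-invasive" if EPI_terminal < threshold else "invasive"


def _four_pl(dose: np.ndarray, bottom: float, top: float,
             log10_ic50: float, slope: float) -> np.ndarray:
    return bottom + (top - bottom) / (
        1.0 + np.power(10.0, slope * (np.log10(dose) - log10_ic50)))


def fit_dose_response(doses, viabilities) -> DoseResponseFit:
    """Least-squares 4PL fit of viability% vs dose on a log scale.

    Requires >= 4 distinct positive doses (the vehicle anchors 100% and
    is handled upstream). When neither the observations nor the fitted
    curve over the observed dose range dips below 50%, the status is
    "ic50-not-reached" and no IC50 is reported. A positive association
    of viability with dose sets ``anomalous_direction``.
    """
    doses = np.asarray(doses, dtype=float)
    viab = np.asarray(viabilities, dtype=float)
    if doses.shape != viab.shape:
        raise InvalidArgumentError("doses and viabilities differ in length")
    keep = doses > 0
    doses, viab = doses[keep], viab[keep]
    if len(np.unique(doses)) < 4:
        raise InsufficientDataError(
            f"need >= 4 distinct positive doses, got {len(np.unique(doses))}")

    order = np.argsort(doses)
    doses, viab = doses[order], viab[order]
    anomalous = bool(np.polyfit(np.log10(doses), viab, 1)[0] > 0)

    p0 = [float(viab.min()), float(viab.max()),
          float(np.median(np.log10(doses))), 1.0]
    lo = [-50.0, 0.0, np.log10(doses.min()) - 3.0, 0.05]
    hi = [150.0, 300.0, np.log10(doses.max()) + 3.0, 10.0]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(
                _four_pl, doses, viab, p0=p0, bounds=(lo, hi), maxfev=20000)
    except (RuntimeError, ValueError):
        status = ("ic50-not-reached" if viab.min() > 50.0 else "fit-failed")
        return DoseResponseFit(doses=doses, viabilities=viab, status=status,
                               anomalous_direction=anomalous)

    fitted = _four_pl(doses, *popt)
    rmse = float(np.sqrt(np.mean((fitted - viab) ** 2)))
    if viab.min() > 50.0 and fitted.min() > 50.0:
        return DoseResponseFit(doses=doses, viabilities=viab,
                               status="ic50-not-reached", rmse=rmse,
                               anomalous_direction=anomalous)

    bottom, top, log_ic50, slope = popt
    se_log = float(np.sqrt(max(pcov[2, 2], 0.0)))
    ci = (10.0 ** (log_ic50 - 1.96 * se_log),
          10.0 ** (log_ic50 + 1.96 * se_log))
    return DoseResponseFit(
        doses=doses, viabilities=viab, status="ok",
        params={"bottom": float(bottom), "top": float(top),
                "ic50": float(10.0 ** log_ic50), "slope": float(slope)},
        ic50_ci=ci, rmse=rmse, anomalous_direction=anomalous)


# ---------------------------------------------------------------------------
# Plate-level summaries
# ---------------------------------------------------------------------------

def _sem(x: pd.Series) -> float:
    return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0


def _well_signals(absorbance: pd.DataFrame) -> pd.DataFrame:
    """Background-subtracted per-(well, day) A570 - A600 signal."""
    ab = absorbance.copy()
    ab["signal"] = ab["A570"] - ab["A600"]
    if "is_blank" in ab.columns:
        blanks = ab[ab["is_blank"].astype(bool)]
        bg = blanks.groupby("day")["signal"].mean() if len(blanks) else None
        ab = ab[~ab["is_blank"].astype(bool)].copy()
        if bg is not None:
            ab["signal"] = ab["signal"] - ab["day"].map(bg).fillna(0.0)
    return ab[["well", "day", "signal"]]


def summarize_plate(
    metrics: pd.DataFrame,
    absorbance: pd.DataFrame,
    layout: pd.DataFrame,
    terminal_day: int = 7,
    first_day: int = 1,
    epi_threshold: float = 0.5,
) -> dict[str, pd.DataFrame]:
    """Reduce per-image metrics + absorbance + layout to endpoint tables.

    Returns a dict of DataFrames:

    * ``timecourse`` - per (condition, dose, day) mean +/- SEM of
      viability%, diameter, roughness, EPI;
    * ``day7_summary`` - terminal-day cross-section with diameter ratio
      and the strict EPI classification;
    * ``tgi`` - per (condition, dose) RTV means and TGI% against the
      same-condition vehicle group;
    * ``dose_response`` - per condition 4PL fit of terminal-day
      viability, including ic50-not-reached status.

    Wells present in the layout but missing from metrics are excluded
    with a warning; they never abort the run.
    """
    required = {"well", "dose_uM", "condition", "replicate"}
    if not required.issubset(layout.columns):
        raise InvalidArgumentError(
            f"layout missing columns {sorted(required - set(layout.columns))}")

    layout = layout.copy()
    metrics = metrics.merge(layout, on="well", how="inner")
    missing = sorted(set(layout["well"]) - set(metrics["well"]))
    if missing:
        warnings.warn(
            f"{len(missing)} wells in layout have no metrics and are "
            f"excluded: {missing[:5]}{'...' if len(missing) > 5 else ''}",
            stacklevel=2)

    signals = _well_signals(absorbance).merge(layout, on="well", how="inner")

    # Viability normalized per (condition, day) to the vehicle group mean.
    ctrl = (signals[signals["dose_uM"] == VEHICLE_DOSE]
            .groupby(["condition", "day"])["signal"].mean()
            .rename("ctrl_signal"))
    signals = signals.join(ctrl, on=["condition", "day"])
    bad_ctrl = signals["ctrl_signal"] <= 0
    if bad_ctrl.any():
        raise DegenerateControlError(
            "vehicle-control signal not positive for some (condition, day)")
    signals["viability_pct"] = 100.0 * signals["signal"] / signals["ctrl_signal"]

    tc_metric = (metrics.groupby(["condition", "dose_uM", "day"])
                 .agg(d_mean=("d", "mean"), d_sem=("d", _sem),
                      roughness_mean=("roughness", "mean"),
                      roughness_sem=("roughness", _sem),
                      EPI_mean=("EPI", "mean"), EPI_sem=("EPI", _sem),
                      n=("well", "nunique"))
                 .reset_index())
    tc_viab = (signals.groupby(["condition", "dose_uM", "day"])
               .agg(viability_mean=("viability_pct", "mean"),
                    viability_sem=("viability_pct", _sem))
               .reset_index())
    timecourse = tc_metric.merge(tc_viab,
                                 on=["condition", "dose_uM", "day"],
                                 how="outer").sort_values(
        ["condition", "dose_uM", "day"]).reset_index(drop=True)

    # Per-well RTV from terminal vs first day, then group means and TGI.
    have_both = (metrics.groupby("well")["day"]
                 .agg(lambda s: first_day in set(s) and terminal_day in set(s)))
    usable = have_both[have_both].index
    skipped = sorted(set(metrics["well"]) - set(usable))
    if skipped:
        warnings.warn(
            f"{len(skipped)} wells lack day {first_day} or day "
            f"{terminal_day} records and are excluded from RTV",
            stacklevel=2)
    mt = metrics[metrics["well"].isin(usable)]
    v_first = mt[mt["day"] == first_day].set_index("well")["V"]
    v_term = mt[mt["day"] == terminal_day].set_index("well")["V"]
    rtv = (v_term / v_first).rename("RTV").reset_index()
    rtv = rtv.merge(layout, on="well")

    tgi_rows = []
    for cond, grp in rtv.groupby("condition"):
        ctrl_grp = grp[grp["dose_uM"] == VEHICLE_DOSE]
        if ctrl_grp.empty:
            warnings.warn(f"no vehicle wells under {cond}; TGI skipped",
                          stacklevel=2)
            continue
        rtv_c = float(ctrl_grp["RTV"].mean())
        for dose, treat in grp[grp["dose_uM"] != VEHICLE_DOSE].groupby("dose_uM"):
            rtv_t = float(treat["RTV"].mean())
            tgi_rows.append(TGIResult(
                dose_uM=float(dose), condition=cond,
                RTV_control=rtv_c, RTV_treatment=rtv_t,
                TGI_percent=tumor_growth_inhibition(rtv_c, rtv_t),
                n_control=len(ctrl_grp), n_treatment=len(treat)))
    tgi = pd.DataFrame([vars(t) for t in tgi_rows],
                       columns=["dose_uM", "condition", "RTV_control",
                                "RTV_treatment", "TGI_percent",
                                "n_control", "n_treatment"])
    tgi = tgi.sort_values(["condition", "dose_uM"]).reset_index(drop=True)

    # Terminal-day cross-section.
    term = metrics[metrics["day"] == terminal_day]
    dratio = (mt[mt["day"] == terminal_day].set_index("well")["d"]
              / mt[mt["day"] == first_day].set_index("well")["d"]
              ).rename("d_ratio").reset_index().merge(layout, on="well")
    d7 = (term.groupby(["condition", "dose_uM"])
          .agg(d_mean=("d", "mean"), d_sem=("d", _sem),
               EPI_mean=("EPI", "mean"), EPI_sem=("EPI", _sem),
               roughness_mean=("roughness", "mean"),
               roughness_sem=("roughness", _sem),
               n=("well", "nunique"))
          .reset_index())
    d7 = d7.merge(
        dratio.groupby(["condition", "dose_uM"])
        .agg(d_ratio_mean=("d_ratio", "mean"), d_ratio_sem=("d_ratio", _sem))
        .reset_index(),
        on=["condition", "dose_uM"], how="left")
    d7 = d7.merge(
        signals[signals["day"] == terminal_day]
        .groupby(["condition", "dose_uM"])
        .agg(viability_mean=("viability_pct", "mean"),
             viability_sem=("viability_pct", _sem))
        .reset_index(),
        on=["condition", "dose_uM"], how="left")
    d7["invasiveness"] = d7["EPI_mean"].map(
        lambda e: classify_invasiveness(e, epi_threshold))
    day7_summary = d7.sort_values(["condition", "dose_uM"]).reset_index(drop=True)

    # Dose-response per condition on terminal-day viability group means.
    dr_rows = []
    for cond, grp in (signals[signals["day"] == terminal_day]
                      .groupby("condition")):
        means = (grp[grp["dose_uM"] > 0]
                 .groupby("dose_uM")["viability_pct"].mean())
        if len(means) < 4:
            dr_rows.append({"condition": cond, "status": "insufficient-data",
                            "ic50_uM": np.nan, "slope": np.nan,
                            "bottom": np.nan, "top": np.nan,
                            "rmse": np.nan, "anomalous_direction": False})
            continue
        fit = fit_dose_response(means.index.to_numpy(), means.to_numpy())
        row = {"condition": cond, "status": fit.status,
               "ic50_uM": np.nan, "slope": np.nan,
               "bottom": np.nan, "top": np.nan,
               "rmse": fit.rmse if fit.rmse is not None else np.nan,
               "anomalous_direction": fit.anomalous_direction}
        if fit.params is not None:
            row.update(ic50_uM=fit.params["ic50"], slope=fit.params["slope"],
                       bottom=fit.params["bottom"], top=fit.params["top"])
        dr_rows.append(row)
    dose_response = pd.DataFrame(
        dr_rows, columns=["condition", "status", "ic50_uM", "slope",
                          "bottom", "top", "rmse", "anomalous_direction"])

    return {"timecourse": timecourse, "day7_summary": day7_summary,
            "tgi": tgi, "dose_response": dose_response}
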