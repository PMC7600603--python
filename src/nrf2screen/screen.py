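"""Dose-response screen analysis: plate normalization, four-parameter
logistic (4PL) fitting, drug sensitivity scores (DSS) and dual-readout
differential hit calling on an isogenic cell-line pair.

The screen compares an NRF2 gain-of-function (GOF) line against its
wild-type (WT) parent across two readouts: CTG (CellTiter-Glo viability,
high signal = live cells) and CTX (CellTox Green cytotoxicity, high signal
= dead cells).  Raw signals are normalized to per-plate DMSO negative and
benzethonium-chloride positive controls onto a common percent-effect scale
(0 = no effect, 100 = full kill).  Each compound's five-point dose series is
fitted with a 4PL curve on log10 dose, summarised as a DSS (normalized area
under the fitted inhibition curve above an activity threshold), and a
compound is a screen hit when DSS(GOF) - DSS(WT) exceeds 5 in BOTH readouts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

log = logging.getLogger(__name__)

NEG_CTRL = "NEG_CTRL"
POS_CTRL = "POS_CTRL"

#: default DSS activity threshold, percent effect
DSS_THRESHOLD = 10.0
#: default hit threshold on delta-DSS (strict: a hit needs > HIT_THRESHOLD
#: in both readouts; a tie at exactly 5 is not a hit)
HIT_THRESHOLD = 5.0

# 4PL parameter bounds, chosen to stabilize 5-point fits:
# bottom in [-10, 20]%, top in [0, 120]%, Hill slope in [0.1, 10],
# EC50 within two decades outside the tested range.
BOTTOM_BOUNDS = (-10.0, 20.0)
TOP_BOUNDS = (0.0, 120.0)
SLOPE_BOUNDS = (0.1, 10.0)
EC50_DECADE_MARGIN = 2.0

_LN10 = math.log(10.0)


@dataclass
class DoseResponseSeries:
    """One compound x one cell line x one readout.

    ``doses`` in nM, strictly increasing; ``response`` is percent effect
    after control normalization (replicates at the same dose allowed —
    ``doses`` and ``response`` are parallel arrays).
    """

    compound: str
    cell_line: str
    readout: str
    doses: np.ndarray
    response: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.doses.shape != self.response.shape:
            raise ValueError("doses and response must be parallel arrays")
        if np.unique(self.doses).size < 2:
            raise ValueError("need >= 2 distinct doses")
        if (self.doses <= 0).any():
            raise ValueError("doses must be positive (nM)")


@dataclass
class LogisticFit:
    """Fitted 4PL parameters: y(x) = bottom + (top-bottom)/(1 + 10^(slope*(log10 ec50 - x)))
    with x = log10 dose."""

    bottom: float
    top: float
    ec50: float  # nM
    hill_slope: float
    converged: bool
    residual_sd: float
    n_params: int = 4  # 3 when the bottom was fixed at 0 (fallback)

    def predict(self, doses) -> np.ndarray:
        x = np.log10(np.asarray(doses, dtype=float))
        return _logistic4(x, self.bottom, self.top, math.log10(self.ec50), self.hill_slope)


@dataclass
class DrugResponseMetrics:
    """Curve-derived response metrics for one series."""

    dss: float
    auc: float  # normalized area under the fitted curve, dimensionless
    ec50: float  # fitted midpoint, nM
    ic50: float  # absolute 50%-effect crossing, nM (nan if censored)
    ic50_censored: bool


def _logistic4(x, bottom, top, log_ec50, slope):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (slope * (log_ec50 - x)))


# ---------------------------------------------------------------------------
# plate normalization
# ---------------------------------------------------------------------------

def normalize_plate(raw: pd.DataFrame, min_controls: int = 3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize raw well signals to percent effect using per-plate controls.

    ``raw`` columns: plate, well, compound, dose_nM, cell_line, readout,
    signal.  Control wells carry NEG_CTRL/POS_CTRL in the compound column.
    Percent effect = 100 * (signal - neg_mean) / (pos_mean - neg_mean),
    which yields percent inhibition for viability readouts (pos < neg) and
    percent kill for toxicity readouts (pos > neg) — in both conventions
    0 = negative-control behaviour and 100 = positive-control behaviour.

    Returns ``(normalized, qc)`` where ``qc`` has one row per
    plate/cell_line/readout with control means, SDs and the Z'-factor.
    """
    required = {"plate", "compound", "dose_nM", "cell_line", "readout", "signal"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")

    out, qc_rows = [], []
    for (plate, line, readout), grp in raw.groupby(["plate", "cell_line", "readout"], sort=False):
        neg = grp.loc[grp["compound"] == NEG_CTRL, "signal"].to_numpy(dtype=float)
        pos = grp.loc[grp["compound"] == POS_CTRL, "signal"].to_numpy(dtype=float)
        if len(neg) < min_controls or len(pos) < min_controls:
            raise ValueError(
                f"plate {plate}/{line}/{readout}: need >= {min_controls} "
                f"negative and positive control wells (got {len(neg)}, {len(pos)})"
            )
        neg_mean, pos_mean = neg.mean(), pos.mean()
        window = pos_mean - neg_mean
        if window == 0:
            raise ValueError(f"plate {plate}/{line}/{readout}: control means equal (dead plate)")
        zprime = 1.0 - 3.0 * (neg.std(ddof=1) + pos.std(ddof=1)) / abs(window)
        qc_rows.append(dict(plate=plate, cell_line=line, readout=readout,
                            neg_mean=neg_mean, pos_mean=pos_mean,
                            neg_sd=neg.std(ddof=1), pos_sd=pos.std(ddof=1),
                            z_prime=zprime))
        wells = grp[~grp["compound"].isin([NEG_CTRL, POS_CTRL])].copy()
        wells["response_pct"] = 100.0 * (wells["signal"] - neg_mean) / window
        out.append(wells)
    normalized = pd.concat(out, ignore_index=True)
    return normalized, pd.DataFrame(qc_rows)


def to_series(normalized: pd.DataFrame) -> list[DoseResponseSeries]:
    """Group a normalized well table into per-(compound, line, readout) series."""
    series = []
    for (comp, line, readout), grp in normalized.groupby(
        ["compound", "cell_line", "readout"], sort=False
    ):
        grp = grp.sort_values("dose_nM")
        series.append(
            DoseResponseSeries(
                compound=comp, cell_line=line, readout=readout,
                doses=grp["dose_nM"].to_numpy(dtype=float),
                response=grp["response_pct"].to_numpy(dtype=float),
            )
        )
    return series


# ---------------------------------------------------------------------------
# 4PL fitting
# ---------------------------------------------------------------------------

def _resid4(p, x, y):
    return _logistic4(x, *p) - y


def _jac4(p, x, y):
    b, t, m, s = p
    u = 10.0 ** (s * (m - x))
    L = 1.0 / (1.0 + u)
    core = u * L * L * _LN10
    return np.column_stack([1.0 - L, L, -(t - b) * s * core,
                            -(t - b) * (m - x) * core])


def fit_logistic4(series: DoseResponseSeries) -> LogisticFit:
    """Least-squares 4PL fit on x = log10 dose with bounded parameters and
    multi-start initialization (analytic Jacobian; extra starts are tried
    only when the first fit leaves large residuals).

    With fewer than 4 distinct doses, or when the full 4-parameter fit fails,
    the bottom is fixed at 0 (3-parameter fallback, flagged via ``n_params``).
    If no fit converges at all, a data-driven flat fit with
    ``converged=False`` is returned so downstream DSS degrades gracefully.
    """
    x = np.log10(series.doses)
    y = series.response
    n_distinct = np.unique(series.doses).size

    m_lo = x.min() - EC50_DECADE_MARGIN
    m_hi = x.max() + EC50_DECADE_MARGIN
    lb4 = np.array([BOTTOM_BOUNDS[0], TOP_BOUNDS[0], m_lo, SLOPE_BOUNDS[0]])
    ub4 = np.array([BOTTOM_BOUNDS[1], TOP_BOUNDS[1], m_hi, SLOPE_BOUNDS[1]])

    # data-driven start: midpoint dose where the response crosses half-range
    y_lo = float(np.clip(y.min(), *BOTTOM_BOUNDS))
    y_hi = float(np.clip(y.max(), *TOP_BOUNDS))
    half = 0.5 * (y.min() + y.max())
    m0 = float(x[np.argmin(np.abs(y - half))])
    starts_m = [m0, 0.5 * (x.min() + x.max()), x.min() + 0.25 * np.ptp(x),
                x.max() - 0.25 * np.ptp(x)]

    def attempt(m_start, fix_bottom: bool):
        p0 = np.clip([y_lo, y_hi, m_start, 1.0], lb4, ub4)
        if fix_bottom:
            res = optimize.least_squares(
                lambda q, xx, yy: _resid4(np.concatenate([[0.0], q]), xx, yy),
                p0[1:],
                jac=lambda q, xx, yy: _jac4(np.concatenate([[0.0], q]), xx, yy)[:, 1:],
                bounds=(lb4[1:], ub4[1:]), args=(x, y),
                xtol=1e-11, ftol=1e-11, gtol=1e-11, max_nfev=60)
            popt = np.concatenate([[0.0], res.x])
        else:
            res = optimize.least_squares(_resid4, p0, jac=_jac4,
                                         bounds=(lb4, ub4), args=(x, y),
                                         xtol=1e-11, ftol=1e-11, gtol=1e-11,
                max_nfev=60)
            popt = res.x
        if not res.success:
            raise RuntimeError("least_squares failed")
        return popt, 2.0 * float(res.cost)

    # "good enough to stop": residual SD under 1% of the response scale
    sse_stop = len(y) * max(1.0, 0.01 * np.ptp(y)) ** 2

    best, best_sse, best_np = None, np.inf, 4
    use_full = n_distinct >= 4
    for m_start in starts_m:
        for fix_bottom in ([False] if use_full else [True]):
            try:
                popt, sse = attempt(m_start, fix_bottom)
            except (RuntimeError, ValueError):
                continue
            n_p = 3 if fix_bottom else 4
            if best is None or sse < best_sse - 1e-12:
                best, best_sse, best_np = popt, sse, n_p
        if best is not None and best_sse <= sse_stop:
            break
    if use_full and best is None:
        # 4-parameter fit unstable everywhere: bottom-fixed fallback
        for m_start in starts_m:
            try:
                popt, sse = attempt(m_start, True)
            except (RuntimeError, ValueError):
                continue
            if best is None or sse < best_sse - 1e-12:
                best, best_sse, best_np = popt, sse, 3

    dof = max(len(y) - best_np, 1) if best is not None else max(len(y) - 1, 1)
    if best is None:
        flat = float(np.clip(np.mean(y), *TOP_BOUNDS))
        resid_sd = float(np.std(y - flat, ddof=0))
        return LogisticFit(bottom=flat, top=flat, ec50=float(np.sqrt(series.doses.min() * series.doses.max())),
                           hill_slope=1.0, converged=False, residual_sd=resid_sd, n_params=0)
    bottom, top, m, slope = best
    if bottom > top:  # bounds allow bottom<=20 with top>=0; enforce ordering
        bottom = top = 0.5 * (bottom + top)
    return LogisticFit(
        bottom=float(bottom), top=float(top), ec50=float(10.0 ** m),
        hill_slope=float(slope), converged=True,
        residual_sd=float(np.sqrt(best_sse / dof)), n_params=best_np,
    )


# ---------------------------------------------------------------------------
# DSS
# ---------------------------------------------------------------------------

def _logistic_area(bottom, top, m, slope, x1, x2):
    """Closed-form integral of the 4PL curve over [x1, x2] in log10 dose.

    d/dx log(1 + 10^(slope*(x-m))) = slope*ln10 * L(x) with
    L(x) = 1/(1 + 10^(slope*(m-x))), so
    int L dx = [logaddexp(0, slope*ln10*(x-m))] / (slope*ln10).
    """
    t2 = np.logaddexp(0.0, slope * _LN10 * (x2 - m))
    t1 = np.logaddexp(0.0, slope * _LN10 * (x1 - m))
    return bottom * (x2 - x1) + (top - bottom) * (t2 - t1) / (slope * _LN10)


def dss(fit: LogisticFit, cmin: float, cmax: float,
        threshold: float = DSS_THRESHOLD) -> DrugResponseMetrics:
    """Drug sensitivity score: normalized area under the fitted response
    curve above the activity threshold.

    DSS = 100 * int_{x in [x1,x2], y >= threshold} (min(y(x), 100) - threshold) dx
              / ((100 - threshold) * (x2 - x1)),
    with x = log10 dose and [x1, x2] = [log10 cmin, log10 cmax].  The fitted
    response is capped at 100% (full kill) inside the integral, so DSS lies
    in [0, 100] by construction.  The integral is evaluated in closed form.
    A curve that never exceeds the threshold scores 0; a curve pinned at
    100% across the range scores 100.  ``auc`` is the plain normalized area
    int y dx / (100 * (x2 - x1)).

    For a non-converged fit use :func:`dss_from_data` instead.
    """
    if not cmin < cmax:
        raise ValueError("cmin must be < cmax")
    x1, x2 = math.log10(cmin), math.log10(cmax)
    b, t, s = fit.bottom, fit.top, fit.hill_slope
    m = math.log10(fit.ec50)

    auc = _logistic_area(b, t, m, s, x1, x2) / (100.0 * (x2 - x1))
    ic50, censored = _crossing(fit, 50.0)

    if t <= threshold:
        return DrugResponseMetrics(0.0, float(auc), fit.ec50, ic50, censored)
    if b >= threshold:
        xl = x1
    else:
        # dose where the curve crosses the threshold (b < threshold < t)
        xc = m - math.log10((t - threshold) / (threshold - b)) / s
        xl = min(max(xc, x1), x2)
    if t > 100.0:
        # dose where the curve crosses the 100% cap; above it the integrand
        # is the constant (100 - threshold)
        xcap = m - math.log10((t - 100.0) / (100.0 - b)) / s
        xu = min(max(xcap, xl), x2)
    else:
        xu = x2
    area = (_logistic_area(b, t, m, s, xl, xu) - threshold * (xu - xl)
            + (100.0 - threshold) * (x2 - xu))
    value = 100.0 * area / ((100.0 - threshold) * (x2 - x1))
    return DrugResponseMetrics(float(np.clip(value, 0.0, 100.0)), float(auc),
                               fit.ec50, ic50, censored)


def _crossing(fit: LogisticFit, level: float) -> tuple[float, bool]:
    """Dose (nM) where the fitted curve reaches an absolute percent effect
    ``level``; (nan, True) when the curve never reaches it."""
    b, t, s = fit.bottom, fit.top, fit.hill_slope
    if not (b < level < t):
        return float("nan"), True
    m = math.log10(fit.ec50)
    x = m - math.log10((t - level) / (level - b)) / s
    return float(10.0 ** x), False


def dss_from_data(doses, responses, threshold: float = DSS_THRESHOLD) -> float:
    """Trapezoid fallback DSS computed directly from normalized responses,
    used when a fit did not converge (and as the numerical oracle in tests)."""
    x = np.log10(np.asarray(doses, dtype=float))
    y = np.clip(np.asarray(responses, dtype=float) - threshold,
                0.0, 100.0 - threshold)
    order = np.argsort(x)
    x, y = x[order], y[order]
    area = np.trapezoid(y, x)
    return float(100.0 * area / ((100.0 - threshold) * (x[-1] - x[0])))


# ---------------------------------------------------------------------------
# screen-level drivers
# ---------------------------------------------------------------------------

def compute_metrics(series_list, threshold: float = DSS_THRESHOLD) -> pd.DataFrame:
    """Fit every series and compute DSS metrics; one row per series."""
    rows = []
    for s in series_list:
        fit = fit_logistic4(s)
        cmin, cmax = float(s.doses.min()), float(s.doses.max())
        if fit.converged:
            met = dss(fit, cmin, cmax, threshold)
            dss_val = met.dss
        else:
            met = DrugResponseMetrics(dss_from_data(s.doses, s.response, threshold),
                                      np.nan, fit.ec50, np.nan, True)
            dss_val = met.dss
        rows.append(dict(
            compound=s.compound, cell_line=s.cell_line, readout=s.readout,
            bottom=fit.bottom, top=fit.top, ec50_nM=fit.ec50,
            hill_slope=fit.hill_slope, converged=fit.converged,
            n_params=fit.n_params, residual_sd_pct=fit.residual_sd,
            dss=dss_val, auc=met.auc, ic50_nM=met.ic50,
            ic50_censored=met.ic50_censored,
        ))
    return pd.DataFrame(rows)


def differential_dss(metrics: pd.DataFrame, wt: str = "WT", gof: str = "GOF",
                     readouts: tuple[str, str] = ("CTG", "CTX"),
                     hit_threshold: float = HIT_THRESHOLD) -> pd.DataFrame:
    """Per-compound delta-DSS = DSS(GOF) - DSS(WT) per readout and the
    dual-readout hit flag (strictly > ``hit_threshold`` in BOTH readouts).

    Compounds missing a cell line or readout are excluded and logged.
    Output is ranked by the minimum delta over readouts, descending.
    """
    pivot = metrics.pivot_table(index="compound", columns=["cell_line", "readout"],
                                values="dss", aggfunc="mean")
    need = [(line, ro) for line in (wt, gof) for ro in readouts]
    have = [c for c in need if c in pivot.columns]
    if len(have) < len(need):
        raise ValueError(f"metrics table missing cell_line/readout combinations: "
                         f"{sorted(set(need) - set(have))}")
    complete = pivot[need].dropna()
    dropped = pivot.index.difference(complete.index)
    if len(dropped):
        log.warning("excluding %d compounds missing in one cell line: %s",
                    len(dropped), list(dropped[:10]))
    res = pd.DataFrame(index=complete.index)
    for ro in readouts:
        res[f"dss_wt_{ro.lower()}"] = complete[(wt, ro)]
        res[f"dss_gof_{ro.lower()}"] = complete[(gof, ro)]
        res[f"delta_dss_{ro.lower()}"] = complete[(gof, ro)] - complete[(wt, ro)]
    deltas = res[[f"delta_dss_{ro.lower()}" for ro in readouts]]
    res["min_delta_dss"] = deltas.min(axis=1)
    res["hit"] = (deltas > hit_threshold).all(axis=1)
    return res.sort_values("min_delta_dss", ascending=False).reset_index()


def analyze_screen(raw: pd.DataFrame, threshold: float = DSS_THRESHOLD,
                   hit_threshold: float = HIT_THRESHOLD):
    """Full screen chain: normalize -> fit -> DSS -> dual-readout hits.

    Returns ``(hits, metrics, qc)`` DataFrames.
    """
    normalized, qc = normalize_plate(raw)
    metrics = compute_metrics(to_series(normalized), threshold=threshold)
    hits = differential_dss(metrics, hit_threshold=hit_threshold)
    return hits, metrics, qc


# ---------------------------------------------------------------------------
# follow-up validation analyses
# ---------------------------------------------------------------------------

def ic50_and_fold(series_wt: DoseResponseSeries, series_gof: DoseResponseSeries
                  ) -> tuple[float, float, float]:
    """Absolute IC50s (dose at 50% of control viability effect) for the two
    lines and the sensitization fold = IC50_WT / IC50_GOF.

    A curve that never reaches 50% yields a censored (nan) IC50 and a nan
    fold.
    """
    ic_wt, cens_wt = _crossing(fit_logistic4(series_wt), 50.0)
    ic_gof, cens_gof = _crossing(fit_logistic4(series_gof), 50.0)
    fold = float("nan") if (cens_wt or cens_gof) else ic_wt / ic_gof
    return ic_wt, ic_gof, fold


def sensitization_analysis(viability: pd.DataFrame, control_inducer: str = "DMSO"
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pharmacological NRF2-inducer sensitization analysis.

    ``viability`` columns: inducer, at9283_nM, replicate, signal (raw
    viability signal).  Each inducer arm is normalized to its own
    no-AT9283 control (set to 100%), then each (inducer, dose) combination
    arm is compared against the (DMSO, same dose) arm with Welch's t-test.

    Returns ``(combo, inducer_alone)``: the combination table with
    mean viability %, SD, n and p-value, and the inducer-alone viability
    (each inducer's no-AT9283 arm relative to the DMSO no-AT9283 arm).
    """
    required = {"inducer", "at9283_nM", "signal"}
    if not required <= set(viability.columns):
        raise ValueError(f"viability table needs columns {sorted(required)}")
    ctrl_means = {}
    for ind, grp in viability.groupby("inducer"):
        ctrl = grp.loc[grp["at9283_nM"] == 0, "signal"]
        if ctrl.empty:
            raise ValueError(f"inducer {ind!r} has no no-AT9283 control arm")
        ctrl_means[ind] = ctrl.mean()
    if control_inducer not in ctrl_means:
        raise ValueError(f"control inducer {control_inducer!r} absent")

    df = viability.copy()
    df["viability_pct"] = [100.0 * s / ctrl_means[i]
                           for i, s in zip(df["inducer"], df["signal"])]

    rows = []
    for (ind, dose), grp in df[df["at9283_nM"] > 0].groupby(["inducer", "at9283_nM"]):
        vals = grp["viability_pct"].to_numpy(dtype=float)
        ref = df[(df["inducer"] == control_inducer) & (df["at9283_nM"] == dose)]
        p = np.nan
        if ind != control_inducer and len(ref) >= 2 and len(vals) >= 2:
            p = float(stats.ttest_ind(vals, ref["viability_pct"], equal_var=False).pvalue)
        rows.append(dict(inducer=ind, at9283_nM=dose,
                         mean_viability_pct=float(vals.mean()),
                         sd_viability_pct=float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                         n=len(vals), p_vs_control=p))
    combo = pd.DataFrame(rows)

    dmso_ctrl = ctrl_means[control_inducer]
    alone = pd.DataFrame(
        [dict(inducer=ind, viability_pct_vs_dmso=100.0 * cm / dmso_ctrl)
         for ind, cm in ctrl_means.items()]
    )
    return combo, alone
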