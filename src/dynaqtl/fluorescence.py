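"""Chlorophyll-fluorescence trait extraction.

Derives NPQ, ΦPSII and Fv/Fm time series from saturating-pulse records,
applies the Fv/Fm quality filter, fits the kinetic models

* NPQ induction under actinic light:  ``NPQ(t) = a * (1 - exp(-b t))``
* NPQ relaxation in darkness:        ``NPQ(t) = a * exp(-b t) + c``
* ΦPSII recovery in darkness:        ``ΦPSII(t) = a * (1 - exp(-b t)) + c``

(the dark clock is re-zeroed at light-off), and computes the summary traits:
the 0–80 s linear NPQ induction slope, NPQ maximum, final NPQ and ΦPSII, the
photoprotection index PI, and the OJIP half-rise time t½ whose reciprocal is
a relative measure of effective PSII antenna size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .simulate import FluorescenceTrace

__all__ = [
    "TraitSeries",
    "ExpFit",
    "derive_timeseries",
    "qc_filter",
    "fit_induction_slope",
    "fit_npq_induction",
    "fit_npq_relaxation",
    "fit_phipsii_recovery",
    "summarize_extremes",
    "compute_pi",
    "ojip_half_rise",
    "trait_table",
    "FVFM_THRESHOLD",
    "PI_PARSES",
]

FVFM_THRESHOLD = 0.70
PI_PARSES = ("nested-ratio", "inner-ratio")


@dataclass
class TraitSeries:
    """Per-pulse NPQ / ΦPSII series of one sample plus Fv/Fm."""

    sample_id: str
    fvfm: float
    t_light: np.ndarray
    npq_light: np.ndarray
    phi_light: np.ndarray
    t_dark: np.ndarray  # re-zeroed at light-off
    npq_dark: np.ndarray
    phi_dark: np.ndarray
    negative_npq_flag: bool = False


@dataclass
class ExpFit:
    """Result of one exponential fit: estimates, residual SS, convergence."""

    a: float
    b: float
    c: float | None
    rss: float
    converged: bool
    n_restarts_used: int = 0


def derive_timeseries(trace: FluorescenceTrace) -> TraitSeries:
    """Compute Fv/Fm and the per-pulse NPQ and ΦPSII series.

    ``Fv/Fm = (Fm - Fo)/Fm``; at each pulse ``NPQ = (Fm - Fm')/Fm'`` and
    ``ΦPSII = (Fm' - F')/Fm'``.  A non-positive Fm' is a data error; Fm' > Fm
    yields a negative NPQ which is retained but flagged.
    """
    fm, fo = trace.fm, trace.fo
    out = {}
    neg = False
    for phase, pulses in (("light", trace.light_pulses), ("dark", trace.dark_pulses)):
        t = np.array([p[0] for p in pulses], dtype=float)
        fp = np.array([p[1] for p in pulses], dtype=float)
        fmp = np.array([p[2] for p in pulses], dtype=float)
        if (fmp <= 0).any():
            raise ValueError(f"{trace.sample_id}: non-positive Fm' in {phase} phase")
        if (fmp > fm).any():
            neg = True
        out[phase] = (t, (fm - fmp) / fmp, (fmp - fp) / fmp)
    return TraitSeries(
        trace.sample_id,
        (fm - fo) / fm,
        *out["light"],
        *out["dark"],
        negative_npq_flag=neg,
    )


def qc_filter(
    traits: pd.DataFrame, fvfm_threshold: float = FVFM_THRESHOLD
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Remove samples whose dark-adapted Fv/Fm falls below the threshold.

    Samples below 0.70 indicate something other than the underlying genetics
    limits photochemistry (damage, poor dark adaptation) and are excluded.
    Returns (kept, removed, report); the report records the removed fraction.
    """
    if "fvfm" not in traits.columns:
        raise ValueError("trait table lacks an 'fvfm' column")
    low = traits["fvfm"] < fvfm_threshold
    kept, removed = traits.loc[~low], traits.loc[low]
    report = {
        "fvfm_threshold": fvfm_threshold,
        "n_total": int(len(traits)),
        "n_removed": int(low.sum()),
        "removed_fraction": float(low.mean()) if len(traits) else 0.0,
        "removed_samples": removed["sample_id"].tolist() if "sample_id" in traits else [],
    }
    return kept, removed, report


def fit_induction_slope(
    t: np.ndarray, npq: np.ndarray, t_max: float = 80.0, include_origin: bool = True
) -> float:
    """OLS slope (NPQ s⁻¹) of NPQ against time over the initial window.

    Points with t <= ``t_max`` enter the fit; the definitional origin point
    NPQ(0) = 0 is included by default (NPQ is zero at light-on).
    """
    t = np.asarray(t, dtype=float)
    npq = np.asarray(npq, dtype=float)
    sel = t <= t_max
    tt, yy = t[sel], npq[sel]
    if include_origin:
        tt = np.concatenate([[0.0], tt])
        yy = np.concatenate([[0.0], yy])
    if len(tt) < 2:
        raise ValueError("need at least 2 points with t <= t_max")
    slope, _ = np.polyfit(tt, yy, 1)
    return float(slope)


def _exp_fit(
    t: np.ndarray,
    y: np.ndarray,
    model: str,
    n_restarts: int = 5,
    rng_seed: int = 0,
) -> ExpFit:
    """Bounded nonlinear least squares with jittered restarts.

    ``model`` is one of ``rise`` (a(1-e^{-bt})), ``decay`` (a e^{-bt} + c) or
    ``rise_offset`` (a(1-e^{-bt}) + c).  Start values: a0 = series range,
    b0 = ln2/60 s⁻¹, c0 = series minimum.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    has_c = model != "rise"
    if len(t) < (4 if has_c else 3):
        raise ValueError("too few points for the exponential fit")
    span = float(y.max() - y.min())
    if span < 1e-12 and model == "rise" and np.abs(y).max() < 1e-12:
        # all-zero series: amplitude 0, rate unidentifiable
        return ExpFit(0.0, np.nan, None, 0.0, converged=False)

    def resid(p):
        if model == "rise":
            a, b = p
            return a * (1.0 - np.exp(-b * t)) - y
        if model == "decay":
            a, b, c = p
            return a * np.exp(-b * t) + c - y
        a, b, c = p
        return a * (1.0 - np.exp(-b * t)) + c - y

    a0 = span if has_c else float(y.max())
    b0 = np.log(2.0) / 60.0
    c0 = float(y.min())
    x0 = np.array([a0, b0, c0][: 2 + has_c])
    if model == "decay" or model == "rise_offset":
        lower = np.array([-np.inf, 0.0, 0.0])
        upper = np.array([np.inf, np.inf, np.inf])
    else:
        lower = np.array([-np.inf, 0.0])
        upper = np.array([np.inf, np.inf])
    x0 = np.clip(x0, lower + 1e-12, None)

    rng = np.random.default_rng(rng_seed)
    best = None
    tried = 0
    for k in range(n_restarts + 1):
        start = x0 if k == 0 else np.clip(x0 * np.exp(rng.normal(0, 0.5, size=x0.size)), lower + 1e-12, None)
        try:
            sol = least_squares(resid, start, bounds=(lower, upper), method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        tried = k
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
        if best is not None and best.success:
            break  # jittered restarts are failure recovery only
    if best is None:
        return ExpFit(np.nan, np.nan, np.nan if has_c else None, np.nan, converged=False, n_restarts_used=tried)
    p = best.x
    rss = float(2.0 * best.cost)
    # unidentifiable rate: flat data fit by a ~ 0
    converged = bool(best.success)
    if abs(p[0]) < 1e-10 and model == "rise":
        converged = False
    return ExpFit(float(p[0]), float(p[1]), float(p[2]) if has_c else None, rss, converged, tried)


def fit_npq_induction(
    t: np.ndarray, npq: np.ndarray, include_origin: bool = True, n_restarts: int = 5
) -> ExpFit:
    """Fit the light-phase NPQ induction model ``a (1 - exp(-b t))``.

    ``a`` is the NPQ induction amplitude and ``b`` the induction rate
    constant (s⁻¹).  The definitional origin NPQ(0)=0 enters the fit.
    """
    t = np.asarray(t, dtype=float)
    npq = np.asarray(npq, dtype=float)
    if len(t) < 4:
        raise ValueError("need >= 4 light-phase points")
    if include_origin and not (len(t) and t[0] == 0.0):
        t = np.concatenate([[0.0], t])
        npq = np.concatenate([[0.0], npq])
    return _exp_fit(t, npq, "rise", n_restarts=n_restarts)


def fit_npq_relaxation(t_dark: np.ndarray, npq: np.ndarray, n_restarts: int = 5) -> ExpFit:
    """Fit dark-phase NPQ relaxation ``a exp(-b t) + c`` (t from light-off).

    ``c >= 0`` absorbs NPQ that does not relax within the dark phase.
    """
    if len(np.asarray(t_dark)) < 4:
        raise ValueError("need >= 4 dark-phase points")
    return _exp_fit(t_dark, npq, "decay", n_restarts=n_restarts)


def fit_phipsii_recovery(
    t_dark: np.ndarray,
    phi: np.ndarray,
    phi_at_light_off: float | None = None,
    n_restarts: int = 5,
) -> ExpFit:
    """Fit dark-phase ΦPSII recovery ``a (1 - exp(-b t)) + c``.

    ``c`` is the ΦPSII value at light-off (the model's t = 0 intercept); if
    ``phi_at_light_off`` is given it is included as the t = 0 data point.
    """
    t_dark = np.asarray(t_dark, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if len(t_dark) < 4:
        raise ValueError("need >= 4 dark-phase points")
    if phi_at_light_off is not None:
        t_dark = np.concatenate([[0.0], t_dark])
        phi = np.concatenate([[phi_at_light_off], phi])
    return _exp_fit(t_dark, phi, "rise_offset", n_restarts=n_restarts)


def summarize_extremes(series: TraitSeries) -> dict[str, float]:
    """NPQ maximum over all pulses; final dark-phase NPQ and ΦPSII."""
    all_npq = np.concatenate([series.npq_light, series.npq_dark])
    if all_npq.size == 0:
        raise ValueError("empty series")
    finals_npq = series.npq_dark[-1] if series.npq_dark.size else series.npq_light[-1]
    finals_phi = series.phi_dark[-1] if series.phi_dark.size else series.phi_light[-1]
    return {
        "npq_max": float(all_npq.max()),
        "npq_final": float(finals_npq),
        "phipsii_final": float(finals_phi),
    }


def compute_pi(
    phipsii_final: float, npq_final: float, fvfm: float, parse: str = "nested-ratio"
) -> float:
    """Photoprotection index from final ΦPSII, final NPQ and Fv/Fm.

    The printed formula's grouping is typographically ambiguous, so both
    defensible parenthesizations are implemented and the parse id is part of
    the call.  With q = 1 - Fv/Fm and s = 1/(1 + NPQf):

    * ``nested-ratio`` (default): PI = ΦPSIIf / ( [1 - q (Fv/Fm + q s)] / s )
    * ``inner-ratio``:            PI = ΦPSIIf / ( 1 - [q (Fv/Fm + q s)] / s )

    The default is the parse under which PI → ΦPSIIf as Fv/Fm → 1 and
    NPQf → 0.  A non-positive denominator yields NaN (flagged missing).
    """
    if not (0.0 < fvfm <= 1.0):
        raise ValueError("fvfm must be in (0, 1]")
    if npq_final < 0:
        raise ValueError("npq_final must be non-negative")
    if parse not in PI_PARSES:
        raise ValueError(f"unknown PI parse {parse!r}; choose from {PI_PARSES}")
    q = 1.0 - fvfm
    s = 1.0 / (1.0 + npq_final)
    inner = q * (fvfm + q * s)
    denom = (1.0 - inner) / s if parse == "nested-ratio" else 1.0 - inner / s
    if denom <= 0:
        warnings.warn("PI denominator non-positive; returning NaN", RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(phipsii_final / denom)


def ojip_half_rise(times: np.ndarray, f: np.ndarray, fo: float | None = None, fj: float | None = None) -> tuple[float, float]:
    """Half-rise time of the fast (OJIP) fluorescence induction.

    t½ is the first time fluorescence reaches Fo + (Fj - Fo)/2, linearly
    interpolated between samples; its reciprocal is a relative estimate of
    the effective PSII antenna size.  Fo defaults to the first sample and
    Fj to the trace maximum.
    """
    times = np.asarray(times, dtype=float)
    f = np.asarray(f, dtype=float)
    if len(times) < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("OJIP times must be strictly increasing with >= 2 samples")
    fo = float(f[0]) if fo is None else float(fo)
    fj = float(f.max()) if fj is None else float(fj)
    if fj <= fo:
        raise ValueError("require Fj > Fo")
    half = fo + (fj - fo) / 2.0
    above = f >= half
    if not above.any():
        raise ValueError("trace never reaches the half-rise level")
    i = int(np.argmax(above))
    if i == 0:
        t_half = float(times[0])
    else:
        t0, t1 = times[i - 1], times[i]
        f0, f1 = f[i - 1], f[i]
        t_half = float(t0 + (half - f0) / (f1 - f0) * (t1 - t0))
    if t_half <= 0:
        raise ValueError("degenerate half-rise time")
    return t_half, 1.0 / t_half


def trait_table(
    traces: list[FluorescenceTrace],
    fvfm_threshold: float = FVFM_THRESHOLD,
    pi_parse: str = "nested-ratio",
    induction_t_max: float = 80.0,
) -> pd.DataFrame:
    """Full per-sample trait table from raw traces (before QC filtering).

    One row per sample: Fv/Fm, induction slope, the three exponential fits,
    extremes, PI, and provenance/flag columns.  Failed fits leave their
    trait columns NaN rather than fabricating values.
    """
    rows = []
    for trace in traces:
        s = derive_timeseries(trace)
        row: dict[str, object] = {
            "sample_id": s.sample_id,
            "fvfm": s.fvfm,
            "negative_npq_flag": s.negative_npq_flag,
            "pi_parse": pi_parse,
        }
        try:
            row["npq_slope"] = fit_induction_slope(s.t_light, s.npq_light, induction_t_max)
        except ValueError:
            row["npq_slope"] = np.nan
        ind = fit_npq_induction(s.t_light, s.npq_light)
        rel = fit_npq_relaxation(s.t_dark, s.npq_dark)
        # the last light-phase ΦPSII anchors the recovery fit at light-off
        phi0 = float(s.phi_light[-1]) if s.phi_light.size else None
        rec = fit_phipsii_recovery(s.t_dark, s.phi_dark, phi_at_light_off=phi0)
        row.update(
            npq_ind_a=ind.a if ind.converged else np.nan,
            npq_ind_b=ind.b if ind.converged else np.nan,
            npq_rel_a=rel.a if rel.converged else np.nan,
            npq_rel_b=rel.b if rel.converged else np.nan,
            npq_rel_c=rel.c if rel.converged else np.nan,
            phi_rec_a=rec.a if rec.converged else np.nan,
            phi_rec_b=rec.b if rec.converged else np.nan,
            phi_rec_c=rec.c if rec.converged else np.nan,
            fit_converged=bool(ind.converged and rel.converged and rec.converged),
        )
        ext = summarize_extremes(s)
        row.update(ext)
        try:
            row["pi"] = compute_pi(ext["phipsii_final"], max(ext["npq_final"], 0.0), s.fvfm, pi_parse)
        except ValueError:
            row["pi"] = np.nan
        row["qc_pass"] = bool(s.fvfm >= fvfm_threshold)
        rows.append(row)
    return pd.DataFrame(rows)
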