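"""%Cleared kinetics: time–activity curves, decay correction, two-phase
exponential fitting and group statistics.

The clearance model is a two-phase exponential association with three free
parameters that starts at 0% and plateaus at 100%:

    pct(t) = 100 * (1 - f * exp(-k_fast * t) - (1 - f) * exp(-k_slow * t))

where ``f`` is the fraction of tracer clearing in the fast phase and
``k_fast >= k_slow`` are rate constants in 1/min.  Group comparisons use
the extra sum-of-squares F test between a pooled ("one curve explains all")
fit and per-group fits; responder frequencies at a %Cleared threshold are
compared with Fisher's exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .volume import DynamicSeries, LabelVolume3D

__all__ = [
    "TimeActivityCurve",
    "ClearanceCurve",
    "TwoPhaseFit",
    "FTestResult",
    "Contingency2x2",
    "extract_tac",
    "decay_correct",
    "percent_cleared",
    "two_phase_model",
    "fit_two_phase",
    "compare_fits_f_test",
    "endpoint_value",
    "classify_responders",
    "fisher_exact",
    "group_summary",
    "GA68_HALF_LIFE_MIN",
]

#: Ga-68 physical half-life in minutes.
GA68_HALF_LIFE_MIN = 68.0

#: Deterministic multi-start grid for the two-phase fit (f, k_fast, k_slow).
MULTISTART_GRID: tuple[tuple[float, float, float], ...] = tuple(
    (f0, kf0, ks0)
    for f0 in (0.25, 0.5, 0.75)
    for kf0 in (0.1, 0.5, 2.0)
    for ks0 in (0.005, 0.02, 0.1)
)


@dataclass
class TimeActivityCurve:
    """ROI activity (µCi) per frame at frame-midpoint times (min)."""

    times_min: np.ndarray
    activity_uci: np.ndarray
    decay_corrected: bool = False
    t_ref_min: float = 0.0

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.activity_uci = np.asarray(self.activity_uci, dtype=float)
        if self.times_min.shape != self.activity_uci.shape:
            raise ValueError("times and activity must have equal length")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.activity_uci < -1e-12):
            raise ValueError("activity must be non-negative")


@dataclass
class ClearanceCurve:
    """%Cleared versus time for one subject/ROI."""

    times_min: np.ndarray
    pct_cleared: np.ndarray
    baseline_uci: float
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.pct_cleared = np.asarray(self.pct_cleared, dtype=float)
        if self.times_min.shape != self.pct_cleared.shape:
            raise ValueError("times and pct_cleared must have equal length")
        if abs(self.pct_cleared[0]) > 1e-9:
            raise ValueError("clearance curves start at 0% by construction")


@dataclass
class TwoPhaseFit:
    """Fitted two-phase exponential association parameters."""

    f: float
    k_fast: float
    k_slow: float
    rss: float
    n_obs: int
    n_params: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("f must be in [0, 1]")
        if not self.k_fast >= self.k_slow >= 0.0:
            raise ValueError("require k_fast >= k_slow >= 0")

    @property
    def df(self) -> int:
        return self.n_obs - self.n_params

    def predict(self, t) -> np.ndarray:
        return two_phase_model(np.asarray(t, dtype=float), self.f, self.k_fast, self.k_slow)


@dataclass
class FTestResult:
    F: float
    df_num: int
    df_den: int
    p: float


@dataclass
class Contingency2x2:
    """Group × responder counts [[a, b], [c, d]] (rows = groups,
    columns = responder / non-responder)."""

    a: int
    b: int
    c: int
    d: int
    threshold_pct: float = 20.0
    row_labels: tuple[str, str] = ("group1", "group2")

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError("counts must be non-negative integers")

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


# ---------------------------------------------------------------------------
# TAC construction

def extract_tac(series: DynamicSeries, roi: LabelVolume3D) -> TimeActivityCurve:
    """Per-frame sum of activity over ROI voxels, at frame midpoints (min)."""
    if not series.geometry.same_geometry(roi):
        raise ValueError("ROI geometry does not match the dynamic series")
    mask = roi.as_bool()
    if not mask.any():
        raise ValueError("empty ROI")
    activity = np.array([float(fr.values[mask].sum()) for fr in series.frames])
    times = series.midpoints_min
    return TimeActivityCurve(times, activity, decay_corrected=False, t_ref_min=float(times[0]))


def decay_correct(
    tac: TimeActivityCurve,
    half_life_min: float = GA68_HALF_LIFE_MIN,
    t_ref_min: float | None = None,
) -> TimeActivityCurve:
    """Remove physical decay: activity(t) × 2^((t − t_ref)/half_life)."""
    if tac.decay_corrected:
        raise ValueError("curve is already decay-corrected")
    t_ref = float(tac.t_ref_min if t_ref_min is None else t_ref_min)
    factor = 2.0 ** ((tac.times_min - t_ref) / half_life_min)
    return TimeActivityCurve(
        tac.times_min.copy(), tac.activity_uci * factor, decay_corrected=True, t_ref_min=t_ref
    )


def percent_cleared(
    tac: TimeActivityCurve, subject_id: str = "", group: str = ""
) -> ClearanceCurve:
    """%Cleared relative to the first post-delivery frame.

    pct(t) = 100 (A0 − A(t)) / A0.  Negative values (net inflow) are kept.
    """
    if not tac.decay_corrected:
        raise ValueError("decay-correct the TAC before computing %Cleared")
    a0 = float(tac.activity_uci[0])
    if a0 <= 0:
        raise ValueError("baseline activity A0 is zero; cannot normalize")
    pct = 100.0 * (a0 - tac.activity_uci) / a0
    return ClearanceCurve(tac.times_min.copy(), pct, a0, subject_id, group)


# ---------------------------------------------------------------------------
# Two-phase exponential fit

def two_phase_model(t, f, k_fast, k_slow):
    """pct(t) = 100 (1 − f e^(−k_fast t) − (1−f) e^(−k_slow t))."""
    t = np.asarray(t, dtype=float)
    return 100.0 * (1.0 - f * np.exp(-k_fast * t) - (1.0 - f) * np.exp(-k_slow * t))


def _pool(curves) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(curves, ClearanceCurve):
        curves = [curves]
    t = np.concatenate([c.times_min for c in curves])
    y = np.concatenate([c.pct_cleared for c in curves])
    return t, y


def fit_two_phase(
    curves: ClearanceCurve | Sequence[ClearanceCurve],
    k_max: float = 50.0,
) -> TwoPhaseFit:
    """Least-squares fit of the two-phase model to one curve or a pooled set.

    A fixed multi-start grid (27 starts) guards against local minima; the
    best residual sum of squares wins, deterministically.  Label switching
    is removed by enforcing k_fast >= k_slow (swap + f -> 1-f).
    """
    t, y = _pool(curves)
    if t.size < 4:
        raise ValueError("need at least 4 observations to fit 3 parameters")
    if t.min() > 1.0:
        warnings.warn("fit assumes curves start near t=0; first time is "
                      f"{t.min():g} min", stacklevel=2)

    def resid(p):
        return two_phase_model(t, *p) - y

    def jac(p):
        f, kf, ks = p
        e1 = np.exp(-kf * t)
        e2 = np.exp(-ks * t)
        return np.column_stack(
            [100.0 * (e2 - e1), 100.0 * f * t * e1, 100.0 * (1 - f) * t * e2]
        )

    bounds = ([0.0, 0.0, 0.0], [1.0, k_max, k_max])
    best = None
    failures = []
    for p0 in MULTISTART_GRID:
        try:
            res = optimize.least_squares(
                resid, p0, jac=jac, bounds=bounds, method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400,
            )
        except Exception as exc:  # pragma: no cover - numerical edge
            failures.append(str(exc))
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0] - 1e-15:
            best = (rss, res.x)
    if best is None:
        raise RuntimeError(
            "two-phase fit failed to converge from any start: " + "; ".join(failures)
        )
    rss, (f, kf, ks) = best
    if kf < ks:
        f, kf, ks = 1.0 - f, ks, kf
    return TwoPhaseFit(float(np.clip(f, 0, 1)), float(kf), float(ks), rss, int(t.size))


def compare_fits_f_test(
    fit_global: TwoPhaseFit, fits_separate: Sequence[TwoPhaseFit]
) -> FTestResult:
    """Extra sum-of-squares F test: pooled fit vs per-group fits.

    F = ((RSS1 − RSS2)/(df1 − df2)) / (RSS2/df2); p from the upper tail of
    the F(df1−df2, df2) distribution.  If the separate fits are (numerically)
    worse than the global fit, F is clamped at 0 with a warning.
    """
    rss1, df1 = fit_global.rss, fit_global.df
    rss2 = float(sum(f.rss for f in fits_separate))
    n2 = sum(f.n_obs for f in fits_separate)
    if n2 != fit_global.n_obs:
        raise ValueError("global and separate fits must use the same observations")
    df2 = n2 - sum(f.n_params for f in fits_separate)
    if df1 <= df2:
        raise ValueError("global model must have more degrees of freedom")
    if rss2 > rss1:
        warnings.warn("separate fits worse than global; clamping F at 0", stacklevel=2)
        fstat = 0.0
    else:
        fstat = ((rss1 - rss2) / (df1 - df2)) / (rss2 / df2)
    p = float(stats.f.sf(fstat, df1 - df2, df2))
    return FTestResult(float(fstat), int(df1 - df2), int(df2), p)


# ---------------------------------------------------------------------------
# Responders, Fisher, summaries

def endpoint_value(curve: ClearanceCurve, endpoint_min: float) -> float | None:
    """%Cleared at the study endpoint (linear interpolation between frames).

    A curve is usable when its frames cover the endpoint to within half a
    frame; otherwise None is returned with a warning.
    """
    t = curve.times_min
    half_step = (t[-1] - t[-2]) / 2.0 if t.size > 1 else 0.0
    if t[-1] + half_step < endpoint_min - 1e-9:
        warnings.warn(
            f"curve {curve.subject_id!r} ends at {t[-1]:g} min, before the "
            f"{endpoint_min:g}-min endpoint; excluded",
            stacklevel=2,
        )
        return None
    return float(np.interp(endpoint_min, t, curve.pct_cleared))


def classify_responders(
    curves_by_group: Mapping[str, Sequence[ClearanceCurve]],
    threshold_pct: float = 20.0,
    endpoint_min: float = 12.0,
) -> Contingency2x2:
    """Responder (strictly > threshold at endpoint) contingency for 2 groups."""
    groups = list(curves_by_group)
    if len(groups) != 2:
        raise ValueError(f"contingency table needs exactly 2 groups, got {len(groups)}")
    rows = []
    for g in groups:
        vals = [endpoint_value(c, endpoint_min) for c in curves_by_group[g]]
        vals = [v for v in vals if v is not None]
        if not vals:
            warnings.warn(f"group {g!r} has no usable curves; zero row", stacklevel=2)
        resp = sum(v > threshold_pct for v in vals)
        rows.append((resp, len(vals) - resp))
    return Contingency2x2(
        rows[0][0], rows[0][1], rows[1][0], rows[1][1],
        threshold_pct=threshold_pct, row_labels=(groups[0], groups[1]),
    )


def fisher_exact(table: Contingency2x2) -> float:
    """Two-sided Fisher's exact p for a 2×2 table.

    Sum of hypergeometric probabilities, over all tables with the observed
    margins, of tables no more probable than the observed one.  A zero
    margin gives p = 1 by convention.
    """
    tab = table.table
    if tab.sum(axis=0).min() == 0 or tab.sum(axis=1).min() == 0:
        warnings.warn("zero margin in contingency table: p = 1 by convention",
                      stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(tab, alternative="two-sided")[1])


def group_summary(
    curves_by_group: Mapping[str, Sequence[ClearanceCurve]],
    endpoint_min: float = 12.0,
) -> dict[str, dict[str, float | None]]:
    """Mean ± SE (sd/sqrt(n)) of endpoint %Cleared per group."""
    out: dict[str, dict[str, float | None]] = {}
    for g, curves in curves_by_group.items():
        vals = [endpoint_value(c, endpoint_min) for c in curves]
        vals = np.array([v for v in vals if v is not None])
        if vals.size == 0:
            raise ValueError(f"group {g!r} has no usable curves")
        se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else None
        out[g] = {"mean": float(vals.mean()), "se": se, "n": int(vals.size)}
    return out
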