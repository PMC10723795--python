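"""FRAP trace normalization, two-component recovery fitting, and T-half.

A raw trace carries the bleached-ROI mean intensity, an extracellular
background ROI, and the whole-nucleus mean intensity over time. The
normalized recovery curve applies double normalization

    F_norm(t) = [(F_roi - F_bg) / (F_whole - F_bg)]
              * [(F_whole - F_bg)_pre / (F_roi - F_bg)_pre]

so that acquisition photobleaching — which attenuates ROI and whole-nucleus
signal alike — cancels exactly, and the pre-bleach level is 1.

The post-bleach curve is fit with a bounded two-component exponential
recovery

    F(t') = F0 + A1 (1 - exp(-k1 t')) + A2 (1 - exp(-k2 t')),   t' = t - t_bleach

with A1, A2 >= 0 and k1 >= k2 > 0 (canonical order: fast component first).
T-half is the time at which the fitted curve reaches halfway from F0 to the
plateau F0 + A1 + A2, found by root bracketing on the fitted model — for a
single component this reduces to ln 2 / k. Two-exponential fits are
notoriously degenerate when the rates are close, so fits with k1/k2 < 1.5
are re-run as single-component and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FRAPTrace",
    "FRAPFit",
    "normalize_trace",
    "fit_recovery",
    "summarize_frap",
    "half_time_of_model",
    "read_trace_csv",
    "write_trace_csv",
]

#: below this rate-separation ratio a two-component fit is treated as
#: unidentifiable and replaced by a single-component fit
RATE_SEPARATION_MIN = 1.5


@dataclass
class FRAPTrace:
    """Raw ROI intensity time series around a bleach event."""

    t: np.ndarray
    f_roi: np.ndarray
    f_bg: np.ndarray
    f_whole: np.ndarray
    bleach_index: int
    trace_id: str = "trace"
    group: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f_roi = np.asarray(self.f_roi, dtype=float)
        self.f_bg = np.asarray(self.f_bg, dtype=float)
        self.f_whole = np.asarray(self.f_whole, dtype=float)
        n = self.t.size
        for name in ("f_roi", "f_bg", "f_whole"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length does not match t")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time points must be strictly increasing")
        if self.bleach_index < 1:
            raise ValueError("at least one pre-bleach frame is required")
        if n - self.bleach_index < 5:
            raise ValueError("at least five post-bleach frames are required")


@dataclass
class FRAPFit:
    """Fitted two-component recovery. Amplitudes in normalized units."""

    a1: float
    a2: float
    k1: float
    k2: float
    f0: float
    t_half: float
    residual_rms: float
    converged: bool
    model: str = "double"  # "double" or "single" (identifiability fallback)
    group: str = ""
    trace_id: str = ""

    @property
    def plateau(self) -> float:
        return self.f0 + self.a1 + self.a2

    def __call__(self, t_post: np.ndarray) -> np.ndarray:
        t_post = np.asarray(t_post, dtype=float)
        return (
            self.f0
            + self.a1 * (1.0 - np.exp(-self.k1 * t_post))
            + self.a2 * (1.0 - np.exp(-self.k2 * t_post))
        )


def normalize_trace(trace: FRAPTrace) -> tuple[np.ndarray, np.ndarray]:
    """Double-normalize a raw trace; returns ``(t, F_norm)`` for all frames.

    Pre-bleach quantities are averaged over all pre-bleach frames. Traces
    whose background meets or exceeds the signal are flagged invalid.
    """
    roi = trace.f_roi - trace.f_bg
    whole = trace.f_whole - trace.f_bg
    pre = slice(0, trace.bleach_index)
    roi_pre = float(roi[pre].mean())
    whole_pre = float(whole[pre].mean())
    if roi_pre <= 0 or whole_pre <= 0 or np.any(whole <= 0):
        raise ValueError("invalid trace: non-positive background-corrected intensity")
    f_norm = (roi / whole) * (whole_pre / roi_pre)
    return trace.t.copy(), f_norm


def _two_exp(t, f0, a1, k1, a2, k2):
    return f0 + a1 * (1 - np.exp(-k1 * t)) + a2 * (1 - np.exp(-k2 * t))


def half_time_of_model(f0: float, a1: float, k1: float, a2: float, k2: float) -> float:
    """Time at which the model reaches halfway from F0 to its plateau."""
    total = a1 + a2
    if total <= 0:
        return math.nan
    if a2 == 0 or k1 == k2:
        return math.log(2.0) / k1
    # root of a1 e^{-k1 t} + a2 e^{-k2 t} = (a1 + a2)/2; bracket then solve
    def deficit(t):
        return a1 * math.exp(-k1 * t) + a2 * math.exp(-k2 * t) - total / 2.0

    hi = math.log(2.0) / min(k1, k2)
    while deficit(hi) > 0:
        hi *= 2.0
    return float(optimize.brentq(deficit, 0.0, hi, xtol=1e-12, rtol=1e-14))


def _fit_single(t_post: np.ndarray, f: np.ndarray) -> tuple[np.ndarray, bool]:
    f0_seed = float(f[0])
    plateau_seed = float(f[max(len(f) - max(len(f) // 10, 2), 1):].mean())
    amp = max(plateau_seed - f0_seed, 1e-6)
    best = None
    for k_seed in np.logspace(-3, 1.5, 12):
        try:
            popt, _ = optimize.curve_fit(
                lambda t, f0, a, k: f0 + a * (1 - np.exp(-k * t)),
                t_post,
                f,
                p0=[f0_seed, amp, k_seed],
                bounds=([-np.inf, 0, 1e-9], [np.inf, np.inf, np.inf]),
                maxfev=5000,
            )
        except RuntimeError:
            continue
        sse = float(np.sum((f - (popt[0] + popt[1] * (1 - np.exp(-popt[2] * t_post)))) ** 2))
        if best is None or sse < best[1]:
            best = (popt, sse)
    if best is None:
        return np.array([f0_seed, amp, 1.0]), False
    return best[0], True


def fit_recovery(
    t_post: np.ndarray,
    f_post: np.ndarray,
    *,
    trace_id: str = "",
    group: str = "",
) -> FRAPFit:
    """Fit the post-bleach curve with the bounded two-component model.

    ``t_post`` is time since bleach (first post-bleach frame at its actual
    offset). Initialization is deterministic: F0 from the first post-bleach
    point, plateau from the mean of the final 10% of points, and rate seeds
    from a coarse log-spaced grid. Non-convergence is reported honestly via
    the ``converged`` flag, never silently.
    """
    t_post = np.asarray(t_post, dtype=float)
    f_post = np.asarray(f_post, dtype=float)
    if t_post.size < 5:
        raise ValueError("at least five post-bleach points are required")
    if not (np.all(np.isfinite(t_post)) and np.all(np.isfinite(f_post))):
        raise ValueError("post-bleach curve must be finite")

    f0_seed = float(f_post[0])
    tail = f_post[max(len(f_post) - max(len(f_post) // 10, 2), 1):]
    plateau_seed = float(tail.mean())
    amp = max(plateau_seed - f0_seed, 1e-6)

    best: tuple[np.ndarray, float] | None = None
    k_grid = np.logspace(-3, 1.5, 10)
    for k1_seed in k_grid:
        for k2_seed in k_grid:
            if k2_seed > k1_seed:
                continue
            p0 = [f0_seed, amp * 0.5, k1_seed, amp * 0.5, k2_seed]
            try:
                popt, _ = optimize.curve_fit(
                    _two_exp,
                    t_post,
                    f_post,
                    p0=p0,
                    bounds=([-np.inf, 0, 1e-9, 0, 1e-9], np.inf),
                    maxfev=2000,
                )
            except RuntimeError:
                continue
            sse = float(np.sum((f_post - _two_exp(t_post, *popt)) ** 2))
            if best is None or sse < best[1]:
                best = (popt, sse)

    converged = best is not None
    if converged:
        f0, a1, k1, a2, k2 = best[0]
    else:
        f0, a1, k1, a2, k2 = f0_seed, amp, 1.0, 0.0, 0.1
    # canonical order: fast component first
    if k2 > k1:
        a1, a2, k1, k2 = a2, a1, k2, k1

    model = "double"
    if a2 > 0 and k2 > 0 and (k1 / k2) < RATE_SEPARATION_MIN:
        # rates too close to separate: refit as single-component, flag it
        (f0, a1, k1), single_ok = _fit_single(t_post, f_post)
        a2, k2 = 0.0, k1
        model = "single"
        converged = converged and single_ok

    resid = f_post - _two_exp(t_post, f0, a1, k1, a2, k2)
    t_half = half_time_of_model(f0, a1, k1, a2, k2)
    return FRAPFit(
        a1=float(a1),
        a2=float(a2),
        k1=float(k1),
        k2=float(k2),
        f0=float(f0),
        t_half=float(t_half),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        converged=bool(converged),
        model=model,
        group=group,
        trace_id=trace_id,
    )


def fit_trace(trace: FRAPTrace) -> FRAPFit:
    """Normalize a raw trace and fit its post-bleach recovery."""
    t, f_norm = normalize_trace(trace)
    post = slice(trace.bleach_index, None)
    t_post = t[post] - t[trace.bleach_index]
    return fit_recovery(t_post, f_norm[post], trace_id=trace.trace_id, group=trace.group)


def summarize_frap(fits: list[FRAPFit], *, reference_group: str | None = None) -> pd.DataFrame:
    """Per-group T-half mean ± SD over converged fits, with Welch t-tests.

    Each non-reference group is compared to ``reference_group`` (default:
    the first group encountered) with a two-sample unequal-variance t-test.
    Groups with fewer than two converged fits get NaN comparisons and a
    notice column.
    """
    frame = pd.DataFrame(
        {
            "group": [f.group for f in fits],
            "t_half": [f.t_half for f in fits],
            "converged": [f.converged for f in fits],
        }
    )
    frame = frame[frame["converged"] & np.isfinite(frame["t_half"])]
    groups = list(dict.fromkeys(frame["group"]))
    if reference_group is None and groups:
        reference_group = groups[0]
    reference = frame.loc[frame["group"] == reference_group, "t_half"].to_numpy()
    rows = []
    for group in groups:
        values = frame.loc[frame["group"] == group, "t_half"].to_numpy()
        row = {
            "group": group,
            "n": len(values),
            "t_half_mean": float(values.mean()) if len(values) else math.nan,
            "t_half_sd": float(values.std(ddof=1)) if len(values) > 1 else math.nan,
            "p_vs_reference": math.nan,
            "notice": "",
        }
        if group != reference_group:
            if len(values) >= 2 and len(reference) >= 2:
                row["p_vs_reference"] = float(
                    stats.ttest_ind(values, reference, equal_var=False).pvalue
                )
            else:
                row["notice"] = "comparison skipped: <2 converged fits"
        rows.append(row)
    return pd.DataFrame(rows)


def read_trace_csv(path, *, trace_id: str = "", group: str = "") -> FRAPTrace:
    """Read a trace CSV with columns t_s, F_roi, F_bg, F_whole and a
    ``# bleach_index=N`` header comment (or a bleach_index column)."""
    bleach_index = None
    with open(path) as handle:
        first = handle.readline()
    if first.startswith("#") and "bleach_index" in first:
        bleach_index = int(first.split("=")[1])
        table = pd.read_csv(path, comment="#")
    else:
        table = pd.read_csv(path)
        if "bleach_index" in table.columns:
            bleach_index = int(table["bleach_index"].iloc[0])
    if bleach_index is None:
        raise ValueError("bleach_index not found in trace file")
    return FRAPTrace(
        t=table["t_s"].to_numpy(),
        f_roi=table["F_roi"].to_numpy(),
        f_bg=table["F_bg"].to_numpy(),
        f_whole=table["F_whole"].to_numpy(),
        bleach_index=bleach_index,
        trace_id=trace_id or str(path),
        group=group,
    )


def write_trace_csv(trace: FRAPTrace, path) -> None:
    with open(path, "w") as handle:
        handle.write(f"# bleach_index={trace.bleach_index}\n")
        pd.DataFrame(
            {
                "t_s": trace.t,
                "F_roi": trace.f_roi,
                "F_bg": trace.f_bg,
                "F_whole": trace.f_whole,
            }
        ).to_csv(handle, index=False)
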