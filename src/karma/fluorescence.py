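"""Fluorescence statistics: FRAP recovery, profile filtering/correlation and
Gaussian peak-distance measurement on 1-D intensity profiles.

FRAP traces are normalised as (I_bl - I_bg) / (I_total - I_bg) — background
subtraction plus bleach correction by whole-cell intensity — then rescaled
so the mean pre-bleach signal is 1.  Recovery of the mobile fraction is
fitted with a single-exponential in half-time parameterisation,
``y(t) = y0 + A * (1 - 2**(-t / tau_half))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks
from scipy.stats import pearsonr

__all__ = [
    "FrapTrace",
    "frap_normalize",
    "FrapRecoveryModel",
    "FrapFitResults",
    "fit_frap_recovery",
    "profile_sd_filter",
    "profile_pearson",
    "fit_profile_peak_distances",
]


@dataclass(frozen=True)
class FrapTrace:
    """Raw FRAP measurement series for one cell.

    ``time`` (s), bleached-region intensity ``I_bl``, extracellular
    background ``I_bg`` and whole-cell intensity ``I_total`` share one frame
    grid; the first ``n_pre`` frames precede the bleach.
    """

    time: np.ndarray
    I_bl: np.ndarray
    I_bg: np.ndarray
    I_total: np.ndarray
    n_pre: int

    def __post_init__(self) -> None:
        for name in ("time", "I_bl", "I_bg", "I_total"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        n = self.time.size
        if not (self.I_bl.size == self.I_bg.size == self.I_total.size == n):
            raise ValueError("all series must have equal length")
        if not 1 <= self.n_pre < n:
            raise ValueError("n_pre must be >= 1 and leave post-bleach frames")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n_pre: int) -> "FrapTrace":
        return cls(df["time"].to_numpy(), df["I_bl"].to_numpy(),
                   df["I_bg"].to_numpy(), df["I_total"].to_numpy(), n_pre)


def frap_normalize(trace: FrapTrace) -> np.ndarray:
    """Background-subtracted, bleach-corrected, pre-bleach-anchored signal.

    Per frame: ``(I_bl - I_bg) / (I_total - I_bg)``, then divided by the
    mean over the pre-bleach frames so the pre-bleach level is 1.
    """
    denom = trace.I_total - trace.I_bg
    bad = denom <= 0
    if bad.any():
        frame = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"I_total <= I_bg at frame {frame}; cannot normalise")
    y = (trace.I_bl - trace.I_bg) / denom
    pre = y[:trace.n_pre].mean()
    if pre <= 0:
        raise ValueError("non-positive mean pre-bleach signal")
    return y / pre


def _recovery(t, y0, A, tau_half):
    return y0 + A * (1.0 - np.exp2(-t / tau_half))


class FrapRecoveryModel:
    """Single-exponential fit of a normalised post-bleach recovery curve.

    Parameters
    ----------
    y : array-like
        Normalised signal (pre-bleach mean 1), post-bleach frames only.
    t : array-like
        Time of each post-bleach frame in seconds, measured from the first
        post-bleach frame.
    y_pre : float
        Pre-bleach level in the same normalisation (1 by construction).
    """

    def __init__(self, y, t, y_pre: float = 1.0):
        self.y = np.asarray(y, dtype=float)
        self.t = np.asarray(t, dtype=float)
        if self.y.size != self.t.size:
            raise ValueError("y and t must have equal length")
        if self.y.size < 10:
            raise ValueError("need at least 10 post-bleach points")
        self.y_pre = float(y_pre)

    def fit(self) -> "FrapFitResults":
        y, t = self.y, self.t
        y0_init = float(y[0])
        A_init = max(float(y[-5:].mean() - y0_init), 1e-6)
        tau_init = max(float(t[-1]) / 4.0, float(np.diff(t).min()))
        span = float(t[-1] - t[0])
        try:
            popt, pcov = curve_fit(
                _recovery, t, y, p0=[y0_init, A_init, tau_init],
                bounds=([-1.0, 0.0, 1e-9], [2.0, 2.0, 100.0 * span]),
                maxfev=10000)
            perr = np.sqrt(np.diag(pcov))
            converged = bool(np.all(np.isfinite(popt)))
        except RuntimeError:
            popt = np.array([y0_init, A_init, tau_init])
            perr = np.full(3, np.nan)
            converged = False
        y0, A, tau = (float(v) for v in popt)
        denom = self.y_pre - y0
        mobile = float(np.clip(A / denom, 0.0, 1.0)) if denom > 1e-12 else 0.0
        return FrapFitResults(model=self, y0=y0, amplitude=A, tau_half=tau,
                              stderr=perr, mobile_fraction=mobile,
                              plateau=y0 + A, converged=converged)


@dataclass
class FrapFitResults:
    """Fitted FRAP recovery parameters."""

    model: FrapRecoveryModel
    y0: float                  # fitted bleach-floor level
    amplitude: float           # recoverable amplitude A
    tau_half: float            # recovery half-time (s)
    stderr: np.ndarray         # standard errors of (y0, A, tau_half)
    mobile_fraction: float     # A / (y_pre - y0), clipped to [0, 1]
    plateau: float             # y0 + A
    converged: bool

    def predict(self, t=None):
        t = self.model.t if t is None else np.asarray(t, dtype=float)
        return _recovery(t, self.y0, self.amplitude, self.tau_half)

    def summary(self) -> str:
        lines = [
            "FRAP recovery fit:  y(t) = y0 + A*(1 - 2^(-t/tau_half))",
            "=" * 52,
            f"n post-bleach frames:  {self.model.y.size}",
            f"y0 (bleach floor):     {self.y0:.4f} +/- {self.stderr[0]:.4f}",
            f"A (amplitude):         {self.amplitude:.4f} +/- {self.stderr[1]:.4f}",
            f"tau_half:              {self.tau_half:.4f} s +/- {self.stderr[2]:.4f}",
            f"plateau:               {self.plateau:.4f}",
            f"mobile fraction:       {self.mobile_fraction:.4f}",
            f"converged:             {self.converged}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.t, self.model.y, ".", alpha=0.6, label="data")
        tt = np.linspace(self.model.t[0], self.model.t[-1], 300)
        ax.plot(tt, self.predict(tt), "-",
                label=f"fit (tau_half={self.tau_half:.2f} s)")
        ax.axhline(1.0, ls="--", color="gray", lw=0.8, label="pre-bleach")
        ax.set_xlabel("time post bleach (s)")
        ax.set_ylabel("normalised intensity")
        ax.legend()
        return ax


def fit_frap_recovery(y_post, t_post, y_pre: float = 1.0) -> FrapFitResults:
    """Fit the recovery model to a normalised post-bleach series."""
    return FrapRecoveryModel(y_post, t_post, y_pre=y_pre).fit()


def profile_sd_filter(profiles, sd_cutoff: float = 200.0):
    """Drop intensity profiles whose sample SD exceeds the cutoff.

    Profiles with large bright foci have high intensity variation along the
    contour; a standard-deviation cutoff (sample SD, n-1 denominator)
    excludes them.  Returns (retained profiles, number excluded).
    """
    kept = [p for p in profiles
            if np.std(np.asarray(p, dtype=float), ddof=1) <= sd_cutoff]
    return kept, len(profiles) - len(kept)


def profile_pearson(green, red) -> float:
    """Pearson correlation between two intensity profiles."""
    g = np.asarray(green, dtype=float)
    r = np.asarray(red, dtype=float)
    if g.size != r.size:
        raise ValueError("profiles must have equal length")
    if g.size < 3:
        raise ValueError("profiles must have length >= 3")
    if np.ptp(g) == 0 or np.ptp(r) == 0:
        raise ValueError("Pearson correlation undefined for a constant profile")
    return float(pearsonr(g, r).statistic)


def _gauss(x, amp, center, sigma, offset):
    return offset + amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def _multi_gauss(x, *params):
    offset = params[-1]
    y = np.full_like(x, offset, dtype=float)
    for i in range(0, len(params) - 1, 3):
        amp, center, sigma = params[i:i + 3]
        y += amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)
    return y


def fit_profile_peak_distances(profile, n_peaks: int, spatial_step: float = 1.0,
                               init_sigma: float = 2.0):
    """Locate peaks on a 1-D profile by Gaussian refinement of local maxima.

    Seeds with the ``n_peaks`` most prominent local maxima, refines each
    with a Gaussian least-squares fit on a window of +/- 3 ``init_sigma``
    samples; seeds with overlapping windows fall back to a joint
    multi-Gaussian fit.  Returns ``(centers, distances)`` — sorted peak
    centers and adjacent-center distances, both in units of
    ``spatial_step``.
    """
    y = np.asarray(profile, dtype=float)
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    x = np.arange(y.size, dtype=float)
    idx, props = find_peaks(y, prominence=0.0)
    if idx.size < n_peaks:
        raise ValueError(
            f"found only {idx.size} local maxima, need {n_peaks}")
    order = np.argsort(props["prominences"])[::-1][:n_peaks]
    seeds = np.sort(idx[order])

    half = 3.0 * init_sigma
    windows = [(s - half, s + half) for s in seeds]
    overlapping = any(windows[i][1] > windows[i + 1][0]
                      for i in range(len(windows) - 1))
    baseline = float(np.min(y))
    centers = []
    if overlapping and n_peaks > 1:
        p0, lo, hi = [], [], []
        for s in seeds:
            p0 += [max(y[int(s)] - baseline, 1e-9), float(s), init_sigma]
            lo += [0.0, 0.0, 1e-3]
            hi += [np.inf, float(y.size - 1), y.size]
        p0.append(baseline)
        lo.append(-np.inf)
        hi.append(np.inf)
        popt, _ = curve_fit(_multi_gauss, x, y, p0=p0, bounds=(lo, hi),
                            maxfev=20000)
        centers = [popt[i + 1] for i in range(0, 3 * n_peaks, 3)]
    else:
        for s in seeds:
            a = max(int(np.floor(s - half)), 0)
            b = min(int(np.ceil(s + half)) + 1, y.size)
            xw, yw = x[a:b], y[a:b]
            p0 = [max(y[int(s)] - baseline, 1e-9), float(s), init_sigma,
                  baseline]
            popt, _ = curve_fit(
                _gauss, xw, yw, p0=p0,
                bounds=([0.0, xw[0], 1e-3, -np.inf],
                        [np.inf, xw[-1], y.size, np.inf]),
                maxfev=20000)
            centers.append(float(popt[1]))
    centers = np.sort(np.asarray(centers)) * spatial_step
    distances = np.diff(centers)
    return centers, distances
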