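"""Synthetic pulse-labeling datasets with known ground truth.

Emulates the statistical structure of the assays the pipeline analyses,
so every estimator can be checked against a known answer:

* heavy/light fragment-ion reports over a pulse time course (0/30/60/90 min,
  3 replicates) with tier-dependent labeling kinetics — early-incorporated
  subunits label faster than the bulk-protein reference, late subunits
  slower;
* label-free multi-bait pulldowns in which an "assembly factor" protein is
  enriched in early- over late-tier baits by a designed factor;
* heavy/light lysate-intermixing mixtures with a designed exchange fraction;
* FRAP traces with known half-time and mobile fraction.

Intensities carry independent multiplicative log-normal noise per fragment
and channel (mean 1, so heavy + light is an unbiased split of the drawn
total); missingness is Bernoulli per fragment x sample.  Every generator is
deterministic under a fixed seed.  Decoy fragments (flagged,
non-proteotypic, b-series, multi-lysine, single-channel) carry corrupted
labeling values so that a filter failure is visible downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fluorescence import FrapTrace
from .io import FRAGMENT_COLUMNS
from .kinetics import KsmParams, bulk_labeling, ksm_forward

__all__ = [
    "SimDesign",
    "make_ground_truth",
    "ground_truth_curves",
    "simulate_karma_dataset",
    "simulate_labelfree_dataset",
    "simulate_intermixing_dataset",
    "simulate_frap_trace",
]

#: default proteins per class, a desk-scale sketch of a pulldown
_DEFAULT_CLASSES = {
    "bait": 1,
    "early_nup": 4,
    "intermediate_nup": 3,
    "late_nup": 4,
    "ntr_reference": 2,
    "bulk": 5,
}

#: default bait -> assembly tier map for the multi-bait label-free screen
_DEFAULT_BAITS = {
    **{f"early_bait_{i}": "early" for i in range(1, 5)},
    **{f"mid_bait_{i}": "intermediate" for i in range(1, 4)},
    **{f"late_bait_{i}": "late" for i in range(1, 5)},
}


@dataclass(frozen=True)
class SimDesign:
    """Experimental design of a simulated dataset.

    Defaults mirror the package's standard assay: a 0/30/60/90 min pulse
    time course in 3 biological replicates, 120 min doubling time, 5
    precursors of 6 y-fragments per protein, log-normal intensity noise
    sigma 0.2 and 5% fragment-wise missingness.
    """

    time_grid: tuple = (0.0, 30.0, 60.0, 90.0)
    replicates: int = 3
    bait: str = "AF1"
    baits: dict = field(default_factory=lambda: dict(_DEFAULT_BAITS))
    classes: dict = field(default_factory=lambda: dict(_DEFAULT_CLASSES))
    n_precursors: int = 5
    n_fragments: int = 6
    doubling_time: float = 120.0
    noise_sigma: float = 0.2
    missingness: float = 0.05
    early_late_factor: float = 5.0
    include_decoys: bool = True

    def __post_init__(self) -> None:
        if 0.0 not in self.time_grid:
            raise ValueError("time grid must include the pre-pulse sample (0)")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if not self.classes or sum(self.classes.values()) == 0:
            raise ValueError("empty design: no proteins requested")

    @property
    def post_times(self) -> tuple:
        return tuple(t for t in self.time_grid if t > 0)


# class-specific kinetic archetypes: (k_a 1/min, phi).  Early subunits enter
# bait reach fast and mature out of it (high phi -> fast labeling); late
# subunits assemble slowly and stay accessible (delayed labeling); the
# bulk/NTR reference follows pure growth dilution.
_CLASS_KINETICS = {
    "bait": (0.2, 0.5),
    "early_nup": (0.2, 0.5),
    "intermediate_nup": (0.01, 0.0),
    "late_nup": (0.004, 0.0),
    "ntr_reference": (None, 0.0),   # bulk curve
    "bulk": (None, 0.0),
}


def make_ground_truth(design: SimDesign, seed: int = 0) -> pd.DataFrame:
    """Draw per-protein ground-truth parameters for a design.

    Returns one row per protein: class, kinetic parameters (k_a, k_m, phi),
    mean abundance (log-normal across proteins around 1e5 a.u.), number of
    precursors, noise scale and missingness rate.
    """
    rng = np.random.default_rng(seed)
    mu = np.log(2.0) / design.doubling_time
    rows = []
    for cls, n in design.classes.items():
        if cls not in _CLASS_KINETICS:
            raise ValueError(f"unknown protein class {cls!r}")
        k_a, phi = _CLASS_KINETICS[cls]
        for i in range(1, n + 1):
            k_m = phi * mu / (1.0 - phi) if phi > 0 else 0.0
            # the bait dominates its own pulldown by an order of magnitude
            mean_abundance = 1e6 if cls == "bait" else 1e5
            rows.append({
                "protein_id": design.bait if cls == "bait" else f"{cls}_{i}",
                "class": cls,
                "k_a": np.nan if k_a is None else k_a,
                "k_m": np.nan if k_a is None else k_m,
                "phi": phi,
                "T_d": design.doubling_time,
                "abundance": float(mean_abundance * rng.lognormal(0.0, 0.5)),
                "n_precursors": design.n_precursors,
                "noise_sigma": design.noise_sigma,
                "missingness": design.missingness,
                "early_late_factor": (design.early_late_factor
                                      if cls == "bait" else 1.0),
            })
    return pd.DataFrame(rows)


def _truth_fl(row, t: np.ndarray) -> np.ndarray:
    """Ground-truth fractional-labeling curve of one protein."""
    if np.isnan(row["k_a"]):
        return bulk_labeling(t, row["T_d"])
    return ksm_forward(t, KsmParams(row["T_d"], row["k_a"], row["k_m"]))


def ground_truth_curves(truth: pd.DataFrame, time_grid) -> pd.DataFrame:
    """Expected FL per protein at each requested time (long format)."""
    t = np.asarray(time_grid, dtype=float)
    rows = []
    for _, row in truth.iterrows():
        fl = np.atleast_1d(_truth_fl(row, t))
        for ti, fli in zip(t, fl):
            rows.append({"protein_id": row["protein_id"], "time_min": ti,
                         "fl_true": float(fli)})
    return pd.DataFrame(rows)


def _lognormal_factor(rng, sigma: float, size) -> np.ndarray:
    """Multiplicative log-normal noise with mean exactly 1."""
    if sigma == 0:
        return np.ones(size)
    return rng.lognormal(-0.5 * sigma ** 2, sigma, size)


def _emit(rows, sample, protein, precursor, series, index, charge, channel,
          intensity, proteotypic=True, excluded=False, lysines=1, missed=0):
    bait, cond, rep, t = sample
    rows.append((bait, cond, rep, t, protein, proteotypic, precursor,
                 series, index, charge, channel, float(intensity),
                 excluded, lysines, missed))


def _frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)


def simulate_karma_dataset(design: SimDesign | None = None,
                           truth: pd.DataFrame | None = None,
                           seed: int = 0):
    """Simulate a pulse-labeling fragment report for one affinity pulldown.

    Returns ``(records, truth)`` — the long-format fragment table in the
    canonical schema, and the per-protein ground truth used to generate it.
    Each protein's expected FL at time t equals its ground-truth curve;
    heavy intensity is total*FL*noise and light total*(1-FL)*noise with
    independent mean-1 log-normal noise; missingness drops fragment x sample
    cells.  Decoy fragments carrying corrupted FL exercise every downstream
    filter when ``design.include_decoys``.
    """
    design = design or SimDesign()
    rng = np.random.default_rng(seed)
    if truth is None:
        truth = make_ground_truth(design, seed=int(rng.integers(2 ** 31)))
    t_grid = np.asarray(design.time_grid, dtype=float)
    samples = [(design.bait, "none", r, t)
               for r in range(1, design.replicates + 1) for t in t_grid]
    rows: list = []
    for _, prot in truth.iterrows():
        fl_by_time = dict(zip(t_grid, np.atleast_1d(_truth_fl(prot, t_grid))))
        sigma, miss = prot["noise_sigma"], prot["missingness"]
        for p in range(1, int(prot["n_precursors"]) + 1):
            pid = f"{prot['protein_id']}_pep{p}/2"
            base = prot["abundance"] * rng.lognormal(0.0, 0.5,
                                                     design.n_fragments)
            for s in samples:
                fl = fl_by_time[s[3]]
                eps_h = _lognormal_factor(rng, sigma, design.n_fragments)
                eps_l = _lognormal_factor(rng, sigma, design.n_fragments)
                gone = rng.random(design.n_fragments) < miss
                for j in range(design.n_fragments):
                    h = 0.0 if gone[j] else base[j] * fl * eps_h[j]
                    light = 0.0 if gone[j] else base[j] * (1 - fl) * eps_l[j]
                    _emit(rows, s, prot["protein_id"], pid, "y", 3 + j, 1,
                          "heavy", h)
                    _emit(rows, s, prot["protein_id"], pid, "y", 3 + j, 1,
                          "light", light)
            if design.include_decoys:
                _add_decoys(rows, rng, samples, prot, pid, fl_by_time, sigma)
    return _frame(rows), truth


def _add_decoys(rows, rng, samples, prot, pid, fl_by_time, sigma) -> None:
    """Fragments every filter must remove, with corrupted labeling."""
    base = prot["abundance"]
    for s in samples:
        fl_bad = 1.0 - fl_by_time[s[3]]    # clearly wrong FL
        eps = _lognormal_factor(rng, sigma, 8)
        # b-series fragment on the real precursor
        _emit(rows, s, prot["protein_id"], pid, "b", 2, 1, "heavy",
              base * fl_bad * eps[0])
        _emit(rows, s, prot["protein_id"], pid, "b", 2, 1, "light",
              base * (1 - fl_bad) * eps[1])
        # two-lysine (missed cleavage) fragment
        _emit(rows, s, prot["protein_id"], pid, "y", 9, 1, "heavy",
              base * fl_bad * eps[2], lysines=2, missed=1)
        _emit(rows, s, prot["protein_id"], pid, "y", 9, 1, "light",
              base * (1 - fl_bad) * eps[3], lysines=2, missed=1)
        # excluded-flag fragment
        _emit(rows, s, prot["protein_id"], pid, "y", 10, 1, "heavy",
              base * fl_bad * eps[4], excluded=True)
        _emit(rows, s, prot["protein_id"], pid, "y", 10, 1, "light",
              base * (1 - fl_bad) * eps[5], excluded=True)
        # heavy-only fragment (never detected in the light channel)
        _emit(rows, s, prot["protein_id"], pid, "y", 11, 1, "heavy",
              base * eps[6])
        _emit(rows, s, prot["protein_id"], pid, "y", 11, 1, "light", 0.0)
        # non-proteotypic precursor
        npid = f"{prot['protein_id']}_shared/2"
        _emit(rows, s, prot["protein_id"], npid, "y", 4, 1, "heavy",
              base * fl_bad * eps[7], proteotypic=False)
        _emit(rows, s, prot["protein_id"], npid, "y", 4, 1, "light",
              base * (1 - fl_bad), proteotypic=False)


def simulate_labelfree_dataset(design: SimDesign | None = None,
                               truth: pd.DataFrame | None = None,
                               seed: int = 0) -> pd.DataFrame:
    """Simulate a single-channel multi-bait label-free fragment report.

    Every protein keeps its mean abundance across baits except the
    assembly-factor protein (the design's ``bait`` entry in the truth
    table), whose abundance is scaled by ``early_late_factor`` in
    early-tier baits, by its square root in intermediate-tier baits and by
    1 in late-tier baits.
    """
    design = design or SimDesign()
    rng = np.random.default_rng(seed)
    if truth is None:
        truth = make_ground_truth(design, seed=int(rng.integers(2 ** 31)))
    if not design.baits:
        raise ValueError("label-free design needs a bait -> tier map")
    bad = {t for t in design.baits.values()
           if t not in {"early", "intermediate", "late"}}
    if bad:
        raise ValueError(f"unknown assembly tier(s): {sorted(bad)}")
    rows: list = []
    for _, prot in truth.iterrows():
        factor = float(prot["early_late_factor"])
        scale_by_tier = {"early": factor, "intermediate": np.sqrt(factor),
                         "late": 1.0}
        sigma, miss = prot["noise_sigma"], prot["missingness"]
        for p in range(1, int(prot["n_precursors"]) + 1):
            pid = f"{prot['protein_id']}_pep{p}/2"
            base = prot["abundance"] * rng.lognormal(0.0, 0.5,
                                                     design.n_fragments)
            for bait, tier in design.baits.items():
                level = scale_by_tier[tier]
                for rep in range(1, design.replicates + 1):
                    s = (bait, "none", rep, 0.0)
                    eps = _lognormal_factor(rng, sigma, design.n_fragments)
                    gone = rng.random(design.n_fragments) < miss
                    for j in range(design.n_fragments):
                        inten = 0.0 if gone[j] else base[j] * level * eps[j]
                        _emit(rows, s, prot["protein_id"], pid, "y", 3 + j, 1,
                              "light", inten)
            if design.include_decoys:
                s0 = (next(iter(design.baits)), "none", 1, 0.0)
                _emit(rows, s0, prot["protein_id"], pid, "y", 12, 1, "light",
                      prot["abundance"] * 10, excluded=True)
                _emit(rows, s0, prot["protein_id"],
                      f"{prot['protein_id']}_shared/2", "y", 4, 1, "light",
                      prot["abundance"] * 10, proteotypic=False)
    return _frame(rows)


def simulate_intermixing_dataset(design: SimDesign | None = None,
                                 mixing_fraction: float = 0.5,
                                 heavy_share: float = 0.5,
                                 seed: int = 0):
    """Simulate a mixed heavy/light lysate pulldown.

    Co-purified background proteins trace the heavy share of the mix
    (FL = ``heavy_share``); bait-bound complex subunits carry
    FL = ``mixing_fraction * heavy_share``.  Returns ``(records,
    subunit_ids)``.
    """
    if not 0.0 <= mixing_fraction <= 1.0:
        raise ValueError("mixing fraction must lie in [0, 1]")
    design = design or SimDesign()
    rng = np.random.default_rng(seed)
    truth = make_ground_truth(design, seed=int(rng.integers(2 ** 31)))
    subunit_classes = {"early_nup", "intermediate_nup", "late_nup"}
    samples = [(design.bait, "none", r, 90.0)
               for r in range(1, design.replicates + 1)]
    rows: list = []
    subunits = []
    for _, prot in truth.iterrows():
        cls = prot["class"]
        if cls == "bait":
            fl = 0.0            # the tagged bait itself is all light
        elif cls in subunit_classes:
            fl = mixing_fraction * heavy_share
            subunits.append(prot["protein_id"])
        else:
            fl = heavy_share    # background traces the mix composition
        sigma, miss = prot["noise_sigma"], prot["missingness"]
        for p in range(1, int(prot["n_precursors"]) + 1):
            pid = f"{prot['protein_id']}_pep{p}/2"
            base = prot["abundance"] * rng.lognormal(0.0, 0.5,
                                                     design.n_fragments)
            for s in samples:
                eps_h = _lognormal_factor(rng, sigma, design.n_fragments)
                eps_l = _lognormal_factor(rng, sigma, design.n_fragments)
                gone = rng.random(design.n_fragments) < miss
                for j in range(design.n_fragments):
                    h = 0.0 if gone[j] else base[j] * fl * eps_h[j]
                    light = 0.0 if gone[j] else base[j] * (1 - fl) * eps_l[j]
                    _emit(rows, s, prot["protein_id"], pid, "y", 3 + j, 1,
                          "heavy", h)
                    _emit(rows, s, prot["protein_id"], pid, "y", 3 + j, 1,
                          "light", light)
    return _frame(rows), sorted(set(subunits))


def simulate_frap_trace(tau_half: float = 2.0, mobile_fraction: float = 1.0,
                        background: float = 50.0, n_pre: int = 20,
                        n_post: int = 200, dt: float = 0.12,
                        noise: float = 0.0, bleach_depth: float = 0.9,
                        seed: int = 0) -> FrapTrace:
    """Simulate a raw FRAP trace with known recovery parameters.

    The normalised post-bleach signal follows
    ``y(t) = y_b + m * (1 - y_b) * (1 - 2**(-t / tau_half))`` where
    ``y_b = 1 - bleach_depth`` is the bleach floor and ``m`` the mobile
    fraction; pre-bleach frames sit at 1.  Gaussian noise of SD ``noise``
    (in normalised units) is added to the bleached-region signal.  Frame
    interval and frame counts default to the standard acquisition
    (120 ms, 20 pre- and 200 post-bleach frames).
    """
    if not 0.0 <= mobile_fraction <= 1.0:
        raise ValueError("mobile fraction must lie in [0, 1]")
    if not 0.0 < bleach_depth <= 1.0:
        raise ValueError("bleach depth must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n = n_pre + n_post
    time = np.arange(n) * dt
    y = np.ones(n)
    t_post = (np.arange(n_post) * dt)
    y_b = 1.0 - bleach_depth
    y[n_pre:] = y_b + mobile_fraction * (1.0 - y_b) * (
        1.0 - np.exp2(-t_post / tau_half))
    if noise > 0:
        y = y + rng.normal(0.0, noise, n)
    span = 1000.0
    I_bg = np.full(n, float(background))
    I_total = I_bg + span
    I_bl = I_bg + span * y
    return FrapTrace(time=time, I_bl=I_bl, I_bg=I_bg, I_total=I_total,
                     n_pre=n_pre)
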