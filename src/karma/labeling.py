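"""Fractional-labeling quantification in affinity pulldowns.

The cascade turns a long-format fragment-ion report into per-protein
fractional-labeling (FL) trajectories:

1. fragment filters — drop flagged fragments, keep proteotypic y-type
   fragments with a single lysine that are detected in both channels;
2. per-precursor aggregation — sum retained fragment intensities per channel
   (or the top-3 most intense, the targeted-assay convention);
3. presence filter — drop precursors not detected in enough replicates at
   every post-labeling time point;
4. fractional labeling FL = H / (H + L) per precursor and sample;
5. per-protein two-pass median: sample medians over all precursors, pruning
   of the highest-RMSE precursors, final median over the survivors.

Time-0 (pre-pulse) samples are carried through and reported but never enter
the presence filter or the RMSE windows.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .io import SAMPLE_KEY

__all__ = [
    "FRAGMENT_ID",
    "filter_fragments",
    "aggregate_precursors",
    "fractional_labeling",
    "presence_filter",
    "protein_labeling",
    "quantify_labeling",
    "replicate_sd_filter",
    "normalize_to_bait",
    "treatment_ratio",
]

logger = logging.getLogger(__name__)

#: columns identifying a fragment ion within a precursor
FRAGMENT_ID = ["protein_id", "precursor_id",
               "fragment_series", "fragment_index", "fragment_charge"]


def filter_fragments(records: pd.DataFrame, detection_threshold: float = 0.0,
                     both_channels_scope: str = "experiment",
                     require_both_channels: bool = True) -> pd.DataFrame:
    """Apply the fragment-level quality filters.

    Keeps proteotypic y-type fragment ions with a single lysine residue that
    are not flagged by the extraction tool and are detected in both the
    heavy and the light channel.  ``both_channels_scope`` controls where the
    two-channel requirement is evaluated: ``"experiment"`` keeps a fragment
    if it has any detection in each channel anywhere in the experiment (the
    default; per-sample zeros then propagate into the precursor sums),
    ``"sample"`` requires detection in both channels within each sample and
    drops the fragment from samples where either channel is absent.
    """
    if both_channels_scope not in {"experiment", "sample"}:
        raise ValueError(f"unknown scope {both_channels_scope!r}")
    df = records
    n0 = len(df)
    df = df[~df["excluded"]]
    n1 = len(df)
    df = df[df["is_proteotypic"]]
    n2 = len(df)
    df = df[df["fragment_series"] == "y"]
    n3 = len(df)
    df = df[df["lysine_count"] == 1]
    n4 = len(df)

    detected = df["intensity"] > detection_threshold
    if not require_both_channels:
        logger.info(
            "fragment filters: %d rows in; excluded-flag removed %d; "
            "non-proteotypic removed %d; non-y removed %d; lysine!=1 "
            "removed %d; two-channel requirement skipped; %d rows out",
            n0, n0 - n1, n1 - n2, n2 - n3, n3 - n4, len(df))
        return df.copy()
    if both_channels_scope == "experiment":
        # fragment kept iff detected at least once in each channel anywhere
        det = df.loc[detected].groupby(FRAGMENT_ID, sort=False)["channel"]
        ok = det.nunique() >= 2
        keys = ok.index[ok]
        idx = pd.MultiIndex.from_frame(df[FRAGMENT_ID])
        df = df[idx.isin(keys)]
    else:
        grp = FRAGMENT_ID + SAMPLE_KEY
        det = df.loc[detected].groupby(grp, sort=False)["channel"]
        ok = det.nunique() >= 2
        keys = ok.index[ok]
        idx = pd.MultiIndex.from_frame(df[grp])
        df = df[idx.isin(keys)]
    logger.info(
        "fragment filters: %d rows in; excluded-flag removed %d; "
        "non-proteotypic removed %d; non-y removed %d; lysine!=1 removed %d; "
        "single-channel removed %d; %d rows out",
        n0, n0 - n1, n1 - n2, n2 - n3, n3 - n4, n4 - len(df), len(df))
    return df.copy()


def aggregate_precursors(records: pd.DataFrame,
                         aggregation: str = "sum_all") -> pd.DataFrame:
    """Aggregate fragment intensities to precursor H / L intensities.

    ``sum_all`` sums every retained fragment per precursor per channel;
    ``top3`` sums the 3 most intense fragments in each channel (the
    targeted-assay convention).  Samples in which a precursor has no
    detected fragment are absent from the output (not-detected convention).

    Returns a table with one row per (sample, precursor) holding ``H``,
    ``L`` and ``fl`` = H / (H + L).
    """
    if aggregation not in {"sum_all", "top3"}:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    grp = SAMPLE_KEY + ["protein_id", "precursor_id", "channel"]
    inten = records["intensity"]
    if aggregation == "top3":
        inten = records.groupby(grp, sort=False)["intensity"].transform(
            lambda s: s.where(s.rank(method="first", ascending=False) <= 3, 0.0))
    sums = (records.assign(intensity=inten)
            .groupby(grp, sort=False)["intensity"].sum()
            .unstack("channel", fill_value=0.0)
            .reset_index())
    for chan, col in (("heavy", "H"), ("light", "L")):
        sums[col] = sums[chan] if chan in sums.columns else 0.0
    prec = sums[SAMPLE_KEY + ["protein_id", "precursor_id", "H", "L"]].copy()
    prec = prec[(prec["H"] + prec["L"]) > 0].reset_index(drop=True)
    prec["fl"] = fractional_labeling(prec["H"], prec["L"])
    return prec


def fractional_labeling(H, L):
    """Fractional labeling FL = H / (H + L); NaN where H + L = 0."""
    H = np.asarray(H, dtype=float)
    L = np.asarray(L, dtype=float)
    if np.any(H < 0) or np.any(L < 0):
        raise ValueError("channel intensities must be non-negative")
    total = H + L
    with np.errstate(invalid="ignore", divide="ignore"):
        fl = np.where(total > 0, H / np.where(total > 0, total, 1.0), np.nan)
    return float(fl) if fl.ndim == 0 else fl


def presence_filter(precursors: pd.DataFrame, min_reps_per_timepoint: int = 2,
                    time_points=None) -> pd.DataFrame:
    """Drop precursors not reproducibly detected across replicates.

    A precursor is retained (within each bait x condition experiment) iff it
    is detected (H + L > 0, i.e. present in the table) in at least
    ``min_reps_per_timepoint`` replicates at *every* post-labeling time
    point.  Time 0 never participates.
    """
    df = precursors
    if time_points is None:
        time_points = sorted(t for t in df["time_min"].unique() if t > 0)
    else:
        time_points = sorted(time_points)
        if any(t <= 0 for t in time_points):
            raise ValueError("time_points must exclude the pre-pulse sample (t=0)")
    if min_reps_per_timepoint == 0 or not time_points:
        return df
    n_reps = df.groupby(["bait", "condition"])["replicate"].nunique()
    if (min_reps_per_timepoint > n_reps).any():
        raise ValueError(
            f"min_reps_per_timepoint={min_reps_per_timepoint} exceeds the "
            f"number of replicates ({int(n_reps.min())}) in the data")
    sub = df[df["time_min"].isin(time_points)]
    counts = (sub.groupby(["bait", "condition", "protein_id", "precursor_id",
                           "time_min"], sort=False)["replicate"]
              .nunique().unstack("time_min", fill_value=0)
              .reindex(columns=time_points, fill_value=0))
    ok = (counts >= min_reps_per_timepoint).all(axis=1)
    keep = ok.index[ok]
    idx = pd.MultiIndex.from_frame(
        df[["bait", "condition", "protein_id", "precursor_id"]])
    out = df[idx.isin(keep)].reset_index(drop=True)
    logger.info("presence filter (min %d reps at each of %s min): "
                "%d precursor-sample rows -> %d",
                min_reps_per_timepoint, time_points, len(df), len(out))
    return out


def _rmse_prune_order(fl_wide: pd.DataFrame, med: pd.Series,
                      weight: pd.Series) -> pd.DataFrame:
    """Per-precursor RMSE from the sample medians and the discard ordering.

    RMSE uses only samples where the precursor has an FL value.  Discard
    priority: highest RMSE first; ties broken by discarding the less intense
    precursor, then the lexicographically later id.
    """
    dev2 = (fl_wide.sub(med, axis=1)) ** 2
    rmse = np.sqrt(dev2.mean(axis=1, skipna=True))
    order = pd.DataFrame({"rmse": rmse, "weight": weight})
    order["pid"] = order.index
    # ascending=False on rmse; among ties keep higher weight (discard last)
    order = order.sort_values(["rmse", "weight", "pid"],
                              ascending=[False, True, False], kind="mergesort")
    return order


def protein_labeling(precursors: pd.DataFrame, discard_fraction: float = 0.5,
                     rmse_time_points=None):
    """Per-protein FL trajectories via the two-pass median with RMSE pruning.

    Pass 1 computes each sample's median FL over all of the protein's
    precursors.  Each precursor's RMSE from those medians (over post-labeling
    samples where it has an FL value) ranks its consistency; the
    ``floor(n * discard_fraction)`` highest-RMSE precursors are discarded and
    the final per-sample FL is the median over the survivors.

    Returns
    -------
    profiles : pandas.DataFrame
        One row per sample x protein: sample key, ``protein_id``, ``fl``,
        ``n_precursors`` (survivors contributing at that sample).
    precursor_qc : pandas.DataFrame
        One row per protein x precursor with its RMSE and ``discarded`` flag.
    """
    if not 0.0 <= discard_fraction < 1.0:
        raise ValueError("discard_fraction must lie in [0, 1)")
    if precursors.empty:
        raise ValueError("no precursors to quantify")
    df = precursors
    if rmse_time_points is None:
        rmse_time_points = sorted(t for t in df["time_min"].unique() if t > 0)

    prof_rows, qc_rows = [], []
    for (bait, cond, protein), sub in df.groupby(
            ["bait", "condition", "protein_id"], sort=True):
        fl_wide = sub.pivot_table(index="precursor_id",
                                  columns=["replicate", "time_min"],
                                  values="fl", aggfunc="first")
        post_cols = [c for c in fl_wide.columns if c[1] in rmse_time_points]
        med_post = fl_wide[post_cols].median(axis=0, skipna=True)
        weight = (sub.groupby("precursor_id")[["H", "L"]].sum().sum(axis=1)
                  .reindex(fl_wide.index))
        order = _rmse_prune_order(fl_wide[post_cols], med_post, weight)
        n_discard = math.floor(len(fl_wide) * discard_fraction)
        discarded = set(order["pid"].iloc[:n_discard])
        qc = order[["pid", "rmse"]].rename(columns={"pid": "precursor_id"})
        qc.insert(0, "protein_id", protein)
        qc.insert(0, "condition", cond)
        qc.insert(0, "bait", bait)
        qc["discarded"] = qc["precursor_id"].isin(discarded)
        qc_rows.append(qc)

        surv = fl_wide.drop(index=list(discarded))
        fl_final = surv.median(axis=0, skipna=True)
        n_contrib = surv.notna().sum(axis=0)
        prof = pd.DataFrame({
            "bait": bait, "condition": cond,
            "replicate": [c[0] for c in surv.columns],
            "time_min": [c[1] for c in surv.columns],
            "protein_id": protein,
            "fl": fl_final.to_numpy(),
            "n_precursors": n_contrib.to_numpy(),
        })
        prof_rows.append(prof)

    profiles = (pd.concat(prof_rows, ignore_index=True)
                .sort_values(["bait", "condition", "protein_id",
                              "replicate", "time_min"], kind="mergesort")
                .reset_index(drop=True))
    profiles.loc[profiles["n_precursors"] == 0, "fl"] = np.nan
    precursor_qc = pd.concat(qc_rows, ignore_index=True)
    return profiles, precursor_qc


def replicate_sd_filter(profiles: pd.DataFrame, max_sd: float) -> pd.DataFrame:
    """Optional automated stand-in for manual curation of noisy trajectories.

    Excludes proteins whose FL standard deviation across replicates exceeds
    ``max_sd`` at any post-labeling time point (within a bait x condition).
    Off by default in :func:`quantify_labeling`; exclusions are logged.
    """
    post = profiles[profiles["time_min"] > 0]
    sd = (post.groupby(["bait", "condition", "protein_id", "time_min"])["fl"]
          .std(ddof=1))
    noisy = sd[sd > max_sd].reset_index()[
        ["bait", "condition", "protein_id"]].drop_duplicates()
    if noisy.empty:
        return profiles
    logger.info("replicate-SD filter (max %.3g): excluding %d protein(s): %s",
                max_sd, len(noisy), ", ".join(noisy["protein_id"]))
    idx = pd.MultiIndex.from_frame(profiles[["bait", "condition", "protein_id"]])
    bad = pd.MultiIndex.from_frame(noisy)
    return profiles[~idx.isin(bad)].reset_index(drop=True)


def quantify_labeling(records: pd.DataFrame, min_reps_per_timepoint: int = 2,
                      discard_fraction: float = 0.5,
                      aggregation: str = "sum_all",
                      both_channels_scope: str = "experiment",
                      detection_threshold: float = 0.0,
                      time_points=None, max_replicate_sd: float | None = None):
    """Run the full labeling-quantification cascade on a fragment report.

    Returns ``(profiles, precursor_qc)`` as in :func:`protein_labeling`.
    """
    frags = filter_fragments(records, detection_threshold=detection_threshold,
                             both_channels_scope=both_channels_scope)
    prec = aggregate_precursors(frags, aggregation=aggregation)
    if prec.empty:
        raise ValueError("no precursors survive the fragment filters")
    prec = presence_filter(prec, min_reps_per_timepoint, time_points)
    if prec.empty:
        raise ValueError("no precursors survive the presence filter")
    profiles, qc = protein_labeling(prec, discard_fraction,
                                    rmse_time_points=time_points)
    if max_replicate_sd is not None:
        profiles = replicate_sd_filter(profiles, max_replicate_sd)
    return profiles, qc


def normalize_to_bait(profiles: pd.DataFrame, bait_protein: str) -> pd.DataFrame:
    """Express each protein's labeling relative to the bait's.

    Replicates are first aggregated by the median per protein per
    (bait, condition, time); each protein's median FL is then divided by the
    bait protein's at the same sample.  Samples where the bait FL is missing
    or zero yield a missing normalised value (logged).
    """
    med = (profiles.groupby(["bait", "condition", "protein_id", "time_min"],
                            sort=True)["fl"].median().reset_index())
    bait = med[med["protein_id"] == bait_protein]
    if bait.empty:
        raise ValueError(f"bait protein {bait_protein!r} not in profiles")
    bait = bait.rename(columns={"fl": "bait_fl"}).drop(columns="protein_id")
    out = med.merge(bait, on=["bait", "condition", "time_min"], how="left")
    bad = out["bait_fl"].isna() | (out["bait_fl"] == 0)
    if bad.any():
        logger.warning("bait FL missing or zero in %d sample group(s); "
                       "normalised values set missing", int(bad.sum()))
    out["fl_norm"] = np.where(bad, np.nan, out["fl"] / out["bait_fl"])
    return out[["bait", "condition", "protein_id", "time_min",
                "fl", "bait_fl", "fl_norm"]]


def treatment_ratio(profiles_treated: pd.DataFrame,
                    profiles_control: pd.DataFrame) -> pd.DataFrame:
    """Per-protein treated/control FL ratio over paired samples.

    Pairs on (protein, replicate, time point) over post-labeling samples
    where both sides are non-missing; pairs with control FL 0 are dropped
    with a warning.  Returns mean ratio, SEM (= sd/sqrt(n), missing for
    n = 1) and n per protein.
    """
    keys = ["protein_id", "replicate", "time_min"]
    t = profiles_treated.loc[profiles_treated["time_min"] > 0,
                             keys + ["fl"]].rename(columns={"fl": "fl_t"})
    c = profiles_control.loc[profiles_control["time_min"] > 0,
                             keys + ["fl"]].rename(columns={"fl": "fl_c"})
    pairs = t.merge(c, on=keys, how="inner").dropna(subset=["fl_t", "fl_c"])
    zero = pairs["fl_c"] == 0
    if zero.any():
        logger.warning("dropping %d pair(s) with zero control FL",
                       int(zero.sum()))
        pairs = pairs[~zero]
    pairs = pairs.assign(ratio=pairs["fl_t"] / pairs["fl_c"])
    g = pairs.groupby("protein_id")["ratio"]
    out = g.agg(mean_ratio="mean", sd="std", n="count").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out[["protein_id", "mean_ratio", "sem", "n"]]
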