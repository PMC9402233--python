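"""Label-free protein abundance across baits and assembly-tier enrichment.

Implements the multi-bait screen that ranks co-purified proteins by their
enrichment in pulldowns of early- versus late-incorporated subunits of a
maturing complex: fragment sums per proteotypic precursor, median
normalisation across samples, top-3 protein intensities, and the
early/late fold-difference score.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import SAMPLE_KEY

__all__ = [
    "precursor_intensities",
    "median_normalize",
    "top3_protein_intensity",
    "tier_enrichment",
    "labelfree_abundance",
]

logger = logging.getLogger(__name__)


def precursor_intensities(records: pd.DataFrame,
                          require_all_replicates: bool = True) -> pd.DataFrame:
    """Sum fragment intensities to precursor intensities (label-free).

    Drops flagged and non-proteotypic fragments, sums the remaining fragment
    intensities per precursor per sample, and (by default) omits precursor
    ions not found in all replicates of every bait in which they occur at
    all — within each bait unless ``require_all_replicates`` is relaxed.
    """
    df = records[~records["excluded"] & records["is_proteotypic"]]
    grp = SAMPLE_KEY + ["protein_id", "precursor_id"]
    prec = (df.groupby(grp, sort=False)["intensity"].sum().reset_index()
            .rename(columns={"intensity": "intensity"}))
    prec = prec[prec["intensity"] > 0].reset_index(drop=True)
    if require_all_replicates:
        n_reps = records.groupby("bait")["replicate"].nunique()
        counts = prec.groupby(["bait", "protein_id", "precursor_id"])[
            "replicate"].nunique()
        full = counts[counts >= counts.index.get_level_values("bait").map(n_reps)]
        idx = pd.MultiIndex.from_frame(prec[["bait", "protein_id",
                                             "precursor_id"]])
        prec = prec[idx.isin(full.index)].reset_index(drop=True)
    return prec


def median_normalize(precursors: pd.DataFrame) -> pd.DataFrame:
    """Median-normalise precursor intensities across samples.

    Each detected intensity is divided by its sample's median and rescaled
    by the grand median of the sample medians, so all sample medians end up
    equal while the data keep their original unit scale.
    """
    df = precursors.copy()
    med = df.groupby(SAMPLE_KEY)["intensity"].transform("median")
    sample_medians = df.groupby(SAMPLE_KEY)["intensity"].median()
    if (sample_medians <= 0).any() or sample_medians.isna().any():
        raise ValueError("every sample must have at least one detected precursor")
    grand = float(sample_medians.median())
    df["intensity"] = df["intensity"] / med * grand
    return df


def top3_protein_intensity(precursors: pd.DataFrame,
                           min_precursors: int = 3) -> pd.DataFrame:
    """Protein intensity = mean of its 3 most intense precursors per sample.

    Proteins characterised by fewer than ``min_precursors`` detected
    precursor ions (over the whole table) are excluded.
    """
    n_prec = precursors.groupby("protein_id")["precursor_id"].nunique()
    keep = n_prec[n_prec >= min_precursors].index
    df = precursors[precursors["protein_id"].isin(keep)]
    grp = SAMPLE_KEY + ["protein_id"]
    top3 = (df.sort_values("intensity", ascending=False)
            .groupby(grp, sort=False).head(3))
    out = top3.groupby(grp, sort=True)["intensity"].mean().reset_index()
    out["n_precursors"] = out["protein_id"].map(n_prec)
    return out


def tier_enrichment(abundances: pd.DataFrame, tier_map: dict[str, str],
                    exclude_proteins=None) -> pd.DataFrame:
    """Early-vs-late assembly-tier enrichment score per protein.

    For each bait the median protein intensity over replicates is taken;
    the score is the fold difference between the median over early-tier
    baits and the median over late-tier baits.  Proteins absent from every
    late-tier pulldown get ``fold = inf`` with ``no_late_signal`` flagged.
    ``exclude_proteins`` (e.g. the complex's own subunits and its transport
    receptors) are dropped before scoring.
    """
    baits = set(abundances["bait"].unique())
    unmapped = baits - set(tier_map)
    if unmapped:
        raise ValueError(f"tier map lacks bait(s): {sorted(unmapped)}")
    early = [b for b in baits if tier_map[b] == "early"]
    late = [b for b in baits if tier_map[b] == "late"]
    if not early or not late:
        raise ValueError("need at least one early- and one late-tier bait")
    df = abundances
    if exclude_proteins is not None:
        df = df[~df["protein_id"].isin(set(exclude_proteins))]
    bait_med = (df.groupby(["protein_id", "bait"])["intensity"]
                .median().unstack("bait"))
    early_med = bait_med.reindex(columns=early).median(axis=1, skipna=True)
    late_med = bait_med.reindex(columns=late).median(axis=1, skipna=True)
    out = pd.DataFrame({
        "protein_id": bait_med.index,
        "early_median": early_med.to_numpy(),
        "late_median": late_med.to_numpy(),
    })
    out = out.dropna(subset=["early_median"]).reset_index(drop=True)
    no_late = out["late_median"].isna() | (out["late_median"] == 0)
    with np.errstate(divide="ignore"):
        out["fold"] = np.where(no_late, np.inf,
                               out["early_median"] / out["late_median"])
    out["no_late_signal"] = no_late
    if no_late.any():
        logger.info("%d protein(s) absent from all late-tier pulldowns "
                    "(fold = inf)", int(no_late.sum()))
    return out.sort_values("fold", ascending=False).reset_index(drop=True)


def labelfree_abundance(records: pd.DataFrame, min_precursors: int = 3,
                        require_all_replicates: bool = True) -> pd.DataFrame:
    """Fragment report -> normalised top-3 protein abundances."""
    prec = precursor_intensities(records,
                                 require_all_replicates=require_all_replicates)
    if prec.empty:
        raise ValueError("no precursors survive the label-free filters")
    prec = median_normalize(prec)
    return top3_protein_intensity(prec, min_precursors=min_precursors)
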