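"""Subunit exchange between complexes during affinity purification.

In a lysate-intermixing assay, heavy-labeled untagged lysate is mixed with
light lysate carrying the affinity-tagged complex before purification.  Any
heavy signal among the bait-bound subunits must have exchanged into tagged
complexes during the procedure.  The intermixing extent normalises each
subunit's fractional labeling to the mean fractional labeling of all
co-purified (background) proteins, which trace the heavy share of the mix:
extent 0 = no exchange, extent ~1 = complete intermixing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import labeling

__all__ = ["intermixing_extent"]

logger = logging.getLogger(__name__)


def intermixing_extent(records: pd.DataFrame, subunit_ids,
                       min_intensity: float = 100.0, min_precursors: int = 4,
                       bait_protein: str | None = None,
                       discard_fraction: float = 0.5) -> pd.DataFrame:
    """Quantify subunit exchange from a mixed-lysate pulldown.

    Runs the labeling-quantification cascade with two extra filters —
    precursor ions whose summed H + L intensity in a sample falls below
    ``min_intensity`` are dropped, and only proteins characterised by at
    least ``min_precursors`` precursor ions are considered — then normalises
    each subunit's FL to the mean FL of all co-purified proteins (the
    subunits themselves and, optionally, the bait excluded from that
    reference).

    Returns one row per subunit with its FL, the bulk reference FL and the
    extent = FL / bulk FL.
    """
    subunit_ids = set(subunit_ids)
    frags = labeling.filter_fragments(records)
    prec = labeling.aggregate_precursors(frags)
    if prec.empty:
        raise ValueError("no precursors survive the fragment filters")
    low = (prec["H"] + prec["L"]) < min_intensity
    if low.any():
        logger.info("intensity filter (<%g): dropping %d precursor-sample "
                    "rows", min_intensity, int(low.sum()))
    prec = prec[~low]
    n_prec = prec.groupby("protein_id")["precursor_id"].nunique()
    keep = n_prec[n_prec >= min_precursors].index
    prec = prec[prec["protein_id"].isin(keep)]
    if prec.empty:
        raise ValueError("no proteins pass the precursor-count filter")
    profiles, _ = labeling.protein_labeling(prec, discard_fraction)

    # one FL per protein: median over all quantified samples
    fl = profiles.groupby("protein_id")["fl"].median()

    # a subunit that never exchanged has no heavy signal anywhere, so the
    # two-channel fragment filter removes it entirely; if it still passes
    # the intensity and precursor-count filters on its light evidence it is
    # a genuine zero-exchange observation (FL = 0), not a missing protein
    absent = subunit_ids - set(fl.index)
    if absent:
        loose = labeling.filter_fragments(
            records[records["protein_id"].isin(absent)],
            require_both_channels=False)
        if not loose.empty:
            lp = labeling.aggregate_precursors(loose)
            lp = lp[(lp["H"] + lp["L"]) >= min_intensity]
            heavy = lp.groupby("protein_id")["H"].sum()
            n_lp = lp.groupby("protein_id")["precursor_id"].nunique()
            for pid in sorted(absent):
                if (n_lp.get(pid, 0) >= min_precursors
                        and heavy.get(pid, 0.0) == 0.0):
                    fl.loc[pid] = 0.0
                    logger.info("subunit %s has no heavy signal anywhere; "
                                "reported as extent 0", pid)
    bulk_ids = [p for p in fl.index
                if p not in subunit_ids and p != bait_protein]
    if not bulk_ids:
        raise ValueError("no co-purified background proteins to normalise to")
    bulk_ref = float(fl.loc[bulk_ids].mean())
    if bulk_ref <= 0:
        raise ValueError("bulk reference fractional labeling is zero")
    present = sorted(subunit_ids & set(fl.index))
    out = pd.DataFrame({
        "protein_id": present,
        "fl": fl.loc[present].to_numpy(dtype=float),
        "bulk_fl": bulk_ref,
    })
    out["extent"] = out["fl"] / out["bulk_fl"]
    logger.info("bulk reference FL = %.4f over %d co-purified protein(s)",
                bulk_ref, len(bulk_ids))
    return out
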