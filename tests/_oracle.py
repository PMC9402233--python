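"""Naive brute-force reimplementation of the labeling cascade.

Plain Python loops and dicts, no vectorisation — an independent oracle for
equivalence tests on small instances.  Mirrors the documented conventions:
experiment-wide two-channel detection, floor(n * discard_fraction) pruning
with ties broken by total intensity then reverse-lexicographic id, RMSE
over post-labeling samples where the precursor has an FL value.
"""

import math
from statistics import median


def oracle_labeling(rows, min_reps=2, discard_fraction=0.5,
                    aggregation="sum_all"):
    """rows: list of dicts in the canonical fragment schema.

    Returns {((bait, cond, rep, time), protein): (fl, n_precursors)}.
    """
    # fragment filters
    kept = [r for r in rows
            if not r["excluded"] and r["is_proteotypic"]
            and r["fragment_series"] == "y" and r["lysine_count"] == 1]
    # two-channel detection, experiment-wide
    frag_channels = {}
    for r in kept:
        fid = (r["protein_id"], r["precursor_id"], r["fragment_series"],
               r["fragment_index"], r["fragment_charge"])
        if r["intensity"] > 0:
            frag_channels.setdefault(fid, set()).add(r["channel"])
    kept = [r for r in kept
            if len(frag_channels.get((r["protein_id"], r["precursor_id"],
                                      r["fragment_series"],
                                      r["fragment_index"],
                                      r["fragment_charge"]), set())) == 2]
    # aggregate to precursor intensities
    frag_int = {}
    for r in kept:
        key = ((r["bait"], r["condition"], r["replicate"], r["time_min"]),
               r["protein_id"], r["precursor_id"], r["channel"])
        frag_int.setdefault(key, []).append(r["intensity"])
    prec = {}
    for key, vals in frag_int.items():
        if aggregation == "top3":
            vals = sorted(vals, reverse=True)[:3]
        prec[key] = sum(vals)
    # build (sample, protein, precursor) -> (H, L), drop undetected
    quant = {}
    for (sample, prot, pid, chan), inten in prec.items():
        h, l = quant.get((sample, prot, pid), (0.0, 0.0))
        if chan == "heavy":
            h += inten
        else:
            l += inten
        quant[(sample, prot, pid)] = (h, l)
    quant = {k: v for k, v in quant.items() if v[0] + v[1] > 0}

    samples = sorted({k[0] for k in quant})
    post_times = sorted({s[3] for s in samples if s[3] > 0})
    # presence filter
    detected = {}
    for (sample, prot, pid) in quant:
        if sample[3] in post_times:
            detected.setdefault((sample[0], sample[1], prot, pid, sample[3]),
                                set()).add(sample[2])
    def present(bait, cond, prot, pid):
        if min_reps == 0:
            return True
        return all(len(detected.get((bait, cond, prot, pid, t), set()))
                   >= min_reps for t in post_times)
    quant = {k: v for k, v in quant.items()
             if present(k[0][0], k[0][1], k[1], k[2])}

    # fractional labeling
    fl = {k: v[0] / (v[0] + v[1]) for k, v in quant.items()}
    # per (bait, cond, protein): two-pass median with RMSE pruning
    groups = {}
    for (sample, prot, pid), val in fl.items():
        groups.setdefault((sample[0], sample[1], prot), {}).setdefault(
            pid, {})[sample] = val
    out = {}
    for (bait, cond, prot), by_prec in groups.items():
        grp_samples = sorted({s for d in by_prec.values() for s in d},
                             key=lambda s: (s[2], s[3]))
        post = [s for s in grp_samples if s[3] > 0]
        med1 = {}
        for s in post:
            vals = [d[s] for d in by_prec.values() if s in d]
            if vals:
                med1[s] = median(vals)
        rmse = {}
        weight = {}
        for pid, d in by_prec.items():
            devs = [(d[s] - med1[s]) ** 2 for s in post
                    if s in d and s in med1]
            rmse[pid] = math.sqrt(sum(devs) / len(devs)) if devs else math.nan
            weight[pid] = sum(sum(quant[(s, prot, pid)])
                              for s in d)
        order = sorted(by_prec, reverse=True)              # pid descending
        order = sorted(order, key=lambda p: (
            -rmse[p] if not math.isnan(rmse[p]) else math.inf, weight[p]))
        n_discard = math.floor(len(by_prec) * discard_fraction)
        dropped = set(order[:n_discard])
        survivors = {p: d for p, d in by_prec.items() if p not in dropped}
        for s in grp_samples:
            vals = [d[s] for d in survivors.values() if s in d]
            out[(s, prot)] = (median(vals) if vals else math.nan, len(vals))
    return out
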