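"""Brute-force reference implementation of the ROH calling rules.

Implements the staged rule set with plain Python loops and explicit
set membership, independently of the vectorized production code, so
the two can be compared exhaustively on small inputs.
"""

from __future__ import annotations

import math


def _mean(het, usable, bins):
    vals = [het[i] for i in bins if usable[i]]
    return sum(vals) / len(vals) if vals else math.nan


def oracle_detect_runs(het, usable, gm, scan_bins=10, candidate_factor=0.25,
                       bin_relax_factor=2.0, roh_ceiling_factor=1.0 / 3.0):
    """Return candidate bin ranges [(a, b), ...] before the coverage rule."""
    n = len(het)
    painted = set()
    if sum(usable) >= scan_bins:
        for i in range(n - scan_bins + 1):
            window = list(range(i, i + scan_bins))
            vals = [het[j] for j in window if usable[j]]
            if vals and sum(vals) / len(vals) < candidate_factor * gm:
                painted.update(window)

    # maximal runs of painted bins
    runs, start = [], None
    for i in range(n + 1):
        if i < n and i in painted:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None

    # break at bins above the relaxation limit
    relaxed_limit = bin_relax_factor * gm
    broken = []
    for a, b in runs:
        cur = []
        for i in range(a, b):
            if usable[i] and het[i] > relaxed_limit:
                if cur:
                    broken.append((cur[0], cur[-1] + 1))
                cur = []
            else:
                cur.append(i)
        if cur:
            broken.append((cur[0], cur[-1] + 1))

    # candidates may not begin or end on unusable or at/above-threshold bins
    def trim(a, b):
        while a < b and not (usable[a] and het[a] < candidate_factor * gm):
            a += 1
        while a < b and not (usable[b - 1] and het[b - 1] < candidate_factor * gm):
            b -= 1
        return (a, b) if a < b else None

    trimmed = [t for r in broken if (t := trim(*r))]

    # greedy left-to-right merging across all-unusable coverage gaps
    merged = []
    for a, b in trimmed:
        if merged:
            pa, pb = merged[-1]
            gap = range(pb, a)
            gap_ok = all(not usable[i] for i in gap)
            if gap_ok and _mean(het, usable, range(pa, b)) <= roh_ceiling_factor * gm:
                merged[-1] = (pa, b)
                continue
        merged.append((a, b))

    # overall ceiling; failing candidates lose the relaxation privilege
    final = []
    for a, b in merged:
        if _mean(het, usable, range(a, b)) <= roh_ceiling_factor * gm:
            final.append((a, b))
            continue
        cur = []
        pieces = []
        for i in range(a, b):
            if usable[i] and het[i] > candidate_factor * gm:
                if cur:
                    pieces.append((cur[0], cur[-1] + 1))
                cur = []
            else:
                cur.append(i)
        if cur:
            pieces.append((cur[0], cur[-1] + 1))
        final.extend(t for p in pieces if (t := trim(*p)))
    return final


def oracle_detect(het, usable, gm, bin_size=10_000, min_covered_fraction=2.0 / 3.0,
                  **kwargs):
    """Full oracle: bin ranges surviving the coverage rule, with stats."""
    out = []
    for a, b in oracle_detect_runs(het, usable, gm, **kwargs):
        span = (b - a) * bin_size
        covered = sum(bin_size for i in range(a, b) if usable[i])
        if covered / span < min_covered_fraction:
            continue
        out.append(
            {
                "start_bin": a,
                "end_bin": b,
                "covered": covered,
                "mean_het": _mean(het, usable, range(a, b)),
            }
        )
    return out


def oracle_membership(positions, intervals):
    """Per-position ROH membership by linear scan over intervals."""
    out = []
    for chrom, pos in positions:
        hit = False
        for ichrom, s, e in intervals:
            if ichrom == chrom and s <= pos < e:
                hit = True
                break
        out.append(hit)
    return out
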