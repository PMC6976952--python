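"""Detection and size classification of runs of homozygosity (ROHs).

An ROH is a contiguous stretch of the genome where an individual's
windowed heterozygosity falls far below their genome-wide average,
indicating the two haplotypes are identical by descent.  Detection works
on the per-bin heterozygosity track produced by :mod:`rohdel.hetwin` and
proceeds in stages:

1.  *Seeding*: every run of ``scan_bins`` consecutive bins (100 kb at
    defaults) whose mean heterozygosity over usable bins is below
    ``candidate_factor`` x the genome mean seeds a candidate; the scan
    window slides by one bin and overlapping qualifying windows are
    unioned.
2.  *Relaxation*: to tolerate local assembly or alignment errors, an
    interior bin of a candidate may carry up to ``bin_relax_factor`` x
    the genome mean, provided the candidate's overall mean stays at or
    below ``roh_ceiling_factor`` x the genome mean.  Bins above the
    relaxation limit break the candidate; candidates whose overall mean
    exceeds the ceiling are re-split with relaxation disabled.
3.  *Trimming*: a candidate cannot begin or end on an unusable bin or on
    a bin at or above the candidate threshold (no outward creep onto
    relaxed bins).
4.  *Bridging*: unusable bins interior to a candidate count toward its
    length but not its covered length; adjacent candidates separated
    only by unusable bins are merged when the merged mean stays under
    the ceiling.
5.  *Coverage*: candidates whose usable bins cover less than
    ``min_covered_fraction`` of their span are dropped.

Detected ROHs are classified by length into short (< 100 kb, ancient
background relatedness), medium (0.1-3 Mb) and long (>= 3 Mb, recent
inbreeding) tracts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SIZE_CLASSES = ("short", "medium", "long")


@dataclass(frozen=True)
class ROHParams:
    scan_bins: int = 10
    candidate_factor: float = 0.25
    bin_relax_factor: float = 2.0
    roh_ceiling_factor: float = 1.0 / 3.0
    min_covered_fraction: float = 2.0 / 3.0
    short_max_bp: int = 100_000
    long_min_bp: int = 3_000_000
    # ">= 3 Mb is long"; set False for a strict > boundary
    long_boundary_inclusive: bool = True

    def __post_init__(self) -> None:
        if self.scan_bins < 1:
            raise ValueError("scan_bins must be >= 1")
        if not (0 < self.candidate_factor < self.roh_ceiling_factor < 1 < self.bin_relax_factor):
            raise ValueError(
                "require 0 < candidate_factor < roh_ceiling_factor < 1 < bin_relax_factor"
            )
        if not 0 < self.min_covered_fraction <= 1:
            raise ValueError("min_covered_fraction must be in (0, 1]")
        if not 0 < self.short_max_bp < self.long_min_bp:
            raise ValueError("size-class bounds out of order")


@dataclass
class ROH:
    """A homozygous tract (0-based half-open, bin-aligned)."""

    chrom: str
    start: int
    end: int
    length: int
    covered_length: int
    mean_het: float
    size_class: str


def classify_roh(length: int, params: ROHParams = ROHParams()) -> str:
    """Assign a size class from tract length in bp."""
    if length <= 0:
        raise ValueError("ROH length must be positive")
    if length < params.short_max_bp:
        return "short"
    if params.long_boundary_inclusive:
        return "long" if length >= params.long_min_bp else "medium"
    return "long" if length > params.long_min_bp else "medium"


def _candidate_runs(het, usable, genome_mean, params):
    """Bin-index runs seeded by qualifying scan windows (stage 1)."""
    n = het.size
    k = params.scan_bins
    if n < k or int(usable.sum()) < k:
        return []
    vals = np.where(usable, np.nan_to_num(het), 0.0)
    cnt = usable.astype(np.int64)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    ccnt = np.concatenate([[0], np.cumsum(cnt)])
    wsum = csum[k:] - csum[:-k]
    wcnt = ccnt[k:] - ccnt[:-k]
    with np.errstate(invalid="ignore", divide="ignore"):
        qualifies = (wcnt > 0) & (wsum / np.maximum(wcnt, 1) < params.candidate_factor * genome_mean)
    painted = np.zeros(n + 1, dtype=np.int64)
    starts = np.nonzero(qualifies)[0]
    np.add.at(painted, starts, 1)
    np.add.at(painted, starts + k, -1)
    mask = np.cumsum(painted[:-1]) > 0
    return _runs_from_mask(mask)


def _runs_from_mask(mask):
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return []
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]]) + 1
    return list(zip(starts.tolist(), ends.tolist()))


def _split_runs(runs, het, usable, limit):
    """Remove usable bins with het > limit, splitting runs (stage 2)."""
    out = []
    for a, b in runs:
        bad = usable[a:b] & (np.nan_to_num(het[a:b]) > limit)
        keep = ~bad
        for s, e in _runs_from_mask(keep):
            out.append((a + s, a + e))
    return out


def _trim(run, het, usable, threshold):
    """Trim edges onto usable bins strictly below the candidate threshold."""
    a, b = run

    def edge_ok(i):
        return usable[i] and het[i] < threshold

    while a < b and not edge_ok(a):
        a += 1
    while a < b and not edge_ok(b - 1):
        b -= 1
    return (a, b) if a < b else None


def _mean_het(a, b, het, usable):
    u = usable[a:b]
    if not u.any():
        return np.nan
    return float(np.nanmean(np.where(u, het[a:b], np.nan)))


def _merge(runs, het, usable, genome_mean, params):
    """Greedy left-to-right bridging of coverage gaps (stage 4).

    Only gaps made entirely of unusable bins are bridged: they carry no
    heterozygosity evidence either way.  Gaps containing usable bins
    were already judged at seeding and stay breaks.
    """
    if not runs:
        return runs
    merged = [runs[0]]
    for a, b in runs[1:]:
        pa, pb = merged[-1]
        gap_ok = not usable[pb:a].any()
        if gap_ok and _mean_het(pa, b, het, usable) <= params.roh_ceiling_factor * genome_mean:
            merged[-1] = (pa, b)
        else:
            merged.append((a, b))
    return merged


def detect_roh(
    windows: pd.DataFrame,
    genome_mean: float,
    params: ROHParams = ROHParams(),
) -> list[ROH]:
    """Call ROHs from a per-sample window track.

    ``windows`` is the :func:`rohdel.hetwin.window_heterozygosity` frame
    (possibly concatenated over chromosomes); ``genome_mean`` is that
    individual's genome-wide mean corrected heterozygosity, the
    reference diversity every threshold is scaled by.
    """
    if genome_mean <= 0:
        raise ValueError("genome mean heterozygosity must be positive")
    rohs: list[ROH] = []
    for chrom, chrom_win in windows.groupby("chrom", sort=False):
        chrom_win = chrom_win.sort_values("start")
        starts = chrom_win["start"].to_numpy()
        ends = chrom_win["end"].to_numpy()
        het = chrom_win["het_corrected"].to_numpy(dtype=float)
        usable = chrom_win["usable"].to_numpy(dtype=bool)

        runs = _candidate_runs(het, usable, genome_mean, params)
        runs = _split_runs(runs, het, usable, params.bin_relax_factor * genome_mean)
        runs = [
            t for r in runs if (t := _trim(r, het, usable, params.candidate_factor * genome_mean))
        ]
        runs = _merge(runs, het, usable, genome_mean, params)

        final = []
        for a, b in runs:
            if _mean_het(a, b, het, usable) <= params.roh_ceiling_factor * genome_mean:
                final.append((a, b))
            else:
                # relaxation not allowed here: re-split at every bin at or
                # above the candidate threshold, then re-trim
                strict = _split_runs([(a, b)], het, usable, params.candidate_factor * genome_mean)
                # _split_runs removes bins strictly above the limit; drop
                # boundary-equal bins via trimming
                for r in strict:
                    t = _trim(r, het, usable, params.candidate_factor * genome_mean)
                    if t is not None:
                        final.append(t)

        for a, b in final:
            span = int(ends[b - 1] - starts[a])
            covered = int((ends[a:b] - starts[a:b])[usable[a:b]].sum())
            if covered / span < params.min_covered_fraction:
                continue
            rohs.append(
                ROH(
                    chrom=str(chrom),
                    start=int(starts[a]),
                    end=int(ends[b - 1]),
                    length=span,
                    covered_length=covered,
                    mean_het=_mean_het(a, b, het, usable),
                    size_class=classify_roh(span, params),
                )
            )
    return rohs


def genome_fraction(
    rohs: list[ROH],
    chrom_lengths,
    size_class: str = "any",
) -> float:
    """Fraction of the genome covered by ROHs of one size class.

    This is the inbreeding summary G_{i,j} = L_ROH / L_genome for
    individual i and class j in {short, medium, long, any}.
    """
    if size_class not in SIZE_CLASSES and size_class != "any":
        raise ValueError(f"unknown size class {size_class!r}")
    total = sum(length for _, length in chrom_lengths)
    if total <= 0:
        raise ValueError("genome length must be positive")
    _check_disjoint(rohs)
    covered = sum(
        r.length for r in rohs if size_class == "any" or r.size_class == size_class
    )
    return covered / total


def _check_disjoint(rohs) -> None:
    by_chrom: dict[str, list] = {}
    for r in rohs:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping ROHs on {chrom}: {(s1, e1)} and {(s2, e2)}")


def roh_summary(rohs: list[ROH], chrom_lengths) -> pd.DataFrame:
    """Per-class count, mean size and genome fraction for one individual."""
    rows = []
    for cls in (*SIZE_CLASSES, "any"):
        sub = [r for r in rohs if cls == "any" or r.size_class == cls]
        rows.append(
            {
                "size_class": cls,
                "n_roh": len(sub),
                "mean_length": float(np.mean([r.length for r in sub])) if sub else 0.0,
                "genome_fraction": genome_fraction(rohs, chrom_lengths, cls),
            }
        )
    return pd.DataFrame(rows)
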