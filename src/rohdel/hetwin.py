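"""Windowed, coverage-corrected heterozygosity.

Individual heterozygosity is summarised in non-overlapping genomic bins
(10 kb by default).  Within a bin, heterozygous calls are counted only at
sites whose read depth passes a per-sample filter, and the raw count is
corrected for the number of sites in the bin that were well covered, so
bins with patchy coverage are comparable to fully covered ones:

    het_corrected = n_het * bin_size / n_wellcovered

Bins with too few well-covered sites are flagged unusable and excluded
from genome-wide averages and from ROH support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

WINDOW_COLUMNS = [
    "chrom",
    "start",
    "end",
    "n_het",
    "n_wellcovered",
    "het_corrected",
    "usable",
]


@dataclass(frozen=True)
class HetParams:
    """Depth filter and binning parameters.

    bin_size
        Width of the non-overlapping windows, in bp.
    min_depth
        Absolute minimum read depth for a genotype call to be trusted.
    max_depth_factor
        Maximum depth expressed as a multiple of the sample's mean
        coverage; calls above it are discarded as likely collapsed
        repeats or mapping artefacts.
    min_wellcovered_sites
        Minimum number of well-covered sites for a bin to be usable.
    """

    bin_size: int = 10_000
    min_depth: int = 4
    max_depth_factor: float = 2.0
    min_wellcovered_sites: int = 1_000

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if self.max_depth_factor <= 0:
            raise ValueError("max_depth_factor must be positive")
        if self.min_wellcovered_sites < 0:
            raise ValueError("min_wellcovered_sites must be >= 0")


@dataclass
class WindowHet:
    """One bin of the per-sample heterozygosity track (0-based half-open)."""

    chrom: str
    start: int
    end: int
    n_het: int
    n_wellcovered: int
    het_corrected: float
    usable: bool


def depth_filter(depth, sample_mean_cov: float, params: HetParams = HetParams()):
    """True where ``min_depth <= depth <= max_depth_factor * mean`` (inclusive).

    ``depth`` may be a scalar or an array; the return matches its shape.
    """
    if sample_mean_cov <= 0:
        raise ValueError("sample mean coverage must be positive")
    depth = np.asarray(depth)
    if np.any(depth < 0):
        raise ValueError("depths must be non-negative")
    ok = (depth >= params.min_depth) & (
        depth <= params.max_depth_factor * sample_mean_cov
    )
    if ok.ndim == 0:
        return bool(ok)
    return ok


def window_heterozygosity(
    positions,
    het_mask,
    depths,
    sample_mean_cov: float,
    chrom: str,
    chrom_length: int,
    params: HetParams = HetParams(),
    wellcovered=None,
) -> pd.DataFrame:
    """Bin one chromosome of one sample into a heterozygosity track.

    Parameters
    ----------
    positions
        0-based site positions, sorted ascending.
    het_mask
        Boolean per site: genotype is heterozygous.
    depths
        Read depth per site.
    sample_mean_cov
        The sample's genome-wide mean coverage (depth-filter reference).
    chrom, chrom_length
        Chromosome name and length in bp; bins tile ``[0, chrom_length)``.
    wellcovered
        Optional per-bin counts of well-covered sites (variant and
        invariant), one entry per bin, e.g. from a per-base depth
        summary or from the simulator.  When absent, the count is
        estimated as the bin's depth-pass fraction at variant sites
        times the bin span (falling back to the chromosome-wide pass
        fraction in bins without variants).

    Returns
    -------
    DataFrame with one row per bin and columns ``WINDOW_COLUMNS``.
    A partial terminal bin is emitted (so bins tile the chromosome)
    but flagged unusable.
    """
    positions = np.asarray(positions, dtype=np.int64)
    het_mask = np.asarray(het_mask, dtype=bool)
    depths = np.asarray(depths)
    if positions.size and np.any(np.diff(positions) < 0):
        raise ValueError("site positions must be sorted ascending")
    if positions.size and (positions[-1] >= chrom_length or positions[0] < 0):
        raise ValueError("site position outside chromosome bounds")

    bin_size = params.bin_size
    n_bins = max(1, -(-chrom_length // bin_size))
    starts = np.arange(n_bins, dtype=np.int64) * bin_size
    ends = np.minimum(starts + bin_size, chrom_length)
    spans = ends - starts
    full = spans == bin_size

    passing = depth_filter(depths, sample_mean_cov, params) if positions.size else np.zeros(0, bool)
    bin_idx = positions // bin_size

    n_sites = np.bincount(bin_idx, minlength=n_bins).astype(np.int64)
    n_pass = np.bincount(bin_idx, weights=passing.astype(float), minlength=n_bins).astype(np.int64)
    n_het = np.bincount(
        bin_idx, weights=(het_mask & passing).astype(float), minlength=n_bins
    ).astype(np.int64)

    if wellcovered is not None:
        n_well = np.asarray(wellcovered, dtype=np.int64)
        if n_well.shape != (n_bins,):
            raise ValueError(
                f"wellcovered track has {n_well.size} bins, expected {n_bins}"
            )
        n_well = np.maximum(n_well, n_het)
    else:
        global_frac = n_pass.sum() / n_sites.sum() if n_sites.sum() else 0.0
        frac = np.where(n_sites > 0, n_pass / np.maximum(n_sites, 1), global_frac)
        n_well = np.maximum(np.rint(frac * spans).astype(np.int64), n_het)

    with np.errstate(divide="ignore", invalid="ignore"):
        het_corrected = np.where(n_well > 0, n_het * bin_size / n_well, np.nan)
    usable = (n_well >= params.min_wellcovered_sites) & full

    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "n_het": n_het,
            "n_wellcovered": n_well,
            "het_corrected": het_corrected,
            "usable": usable,
        }
    )


def genome_mean_het(windows: pd.DataFrame, exclude_rohs=None) -> float:
    """Mean ``het_corrected`` over usable bins.

    ``exclude_rohs`` is an optional iterable of ``(chrom, start, end)``
    intervals (0-based half-open); bins overlapping any of them are left
    out, giving the heterozygosity of the genome outside ROHs.
    """
    usable = windows[windows["usable"]]
    if exclude_rohs is not None:
        keep = np.ones(len(usable), dtype=bool)
        for chrom, start, end in exclude_rohs:
            keep &= ~(
                (usable["chrom"].to_numpy() == chrom)
                & (usable["start"].to_numpy() < end)
                & (usable["end"].to_numpy() > start)
            )
        usable = usable[keep]
    if usable.empty:
        raise ValueError("no usable windows to average")
    return float(usable["het_corrected"].mean())


def windows_to_records(windows: pd.DataFrame) -> list[WindowHet]:
    """View a window track as a list of :class:`WindowHet` records."""
    return [WindowHet(**row) for row in windows[WINDOW_COLUMNS].to_dict("records")]
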