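"""Burden statistics for deleterious variation.

Four inferential summaries over polarized, functionally classified
genotypes:

*  a likelihood-ratio test (LRT) for a difference between two
   management groups in the per-individual proportion of
   homozygous-derived genotypes within a functional class;
*  genetic load as the per-individual ratio of deleterious to
   synonymous sites, separately for heterozygous and homozygous-derived
   genotypes;
*  the derived-allele-frequency (DAF) spectrum per functional class,
   binned into ten frequency classes;
*  the enrichment of ROHs for damaging homozygous-derived variants —
   counts inside/outside each ROH size class, compared against the
   genome fraction G_{i,j} covered by that class.

The LRT models each genotype as a Bernoulli draw: individual i carries
x_i homozygous-derived genotypes among n_i non-missing genotypes at the
class's sites.  Under the null both groups share one proportion p;
under the alternative each group has its own.  The statistic
Lambda = -2 (ll_null - ll_alt) is chi-square with 1 df under the null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .rohfind import ROH, SIZE_CLASSES, genome_fraction

ENRICHMENT_CLASSES = (*SIZE_CLASSES, "any")


@dataclass(frozen=True)
class LRTResult:
    groups: tuple[str, str]
    p_pooled: float
    p_group: dict[str, float]
    loglik_null: float
    loglik_alt: float
    lam: float
    p_value: float


@dataclass
class LoadResult:
    per_individual: pd.DataFrame  # sample, group, het_load, hom_load
    group_means: pd.DataFrame  # group, het_load, hom_load, n


@dataclass
class SFSResult:
    bin_edges: np.ndarray = field(default_factory=lambda: np.linspace(0, 1, 11))
    counts: dict[str, np.ndarray] = field(default_factory=dict)


def _bernoulli_loglik(x: np.ndarray, n: np.ndarray, p: float) -> float:
    """Sum of per-genotype Bernoulli log-likelihoods; 0*log(0) == 0."""
    x_tot, n_tot = float(x.sum()), float(n.sum())
    ll = 0.0
    if x_tot > 0:
        if p == 0:
            return -np.inf
        ll += x_tot * np.log(p)
    if n_tot - x_tot > 0:
        if p == 1:
            return -np.inf
        ll += (n_tot - x_tot) * np.log1p(-p)
    return ll


def lrt_homozygosity(counts: pd.DataFrame, group_a: str, group_b: str) -> LRTResult:
    """LRT for differing homozygous-derived proportions between two groups.

    ``counts`` needs columns ``sample``, ``group``, ``x`` (hom-derived
    genotypes) and ``n`` (non-missing genotypes); only rows of the two
    named groups are used.  MLEs are pooled ratios (sum x / sum n),
    per group under the alternative.
    """
    sub = counts[counts["group"].isin([group_a, group_b])]
    if (sub["x"] > sub["n"]).any() or (sub["x"] < 0).any():
        raise ValueError("need 0 <= x <= n")
    xs, ns = {}, {}
    for g in (group_a, group_b):
        rows = sub[sub["group"] == g]
        if rows.empty or rows["n"].sum() == 0:
            raise ValueError(f"group {g!r} has no genotypes")
        xs[g] = rows["x"].to_numpy(float)
        ns[g] = rows["n"].to_numpy(float)

    x_all = np.concatenate([xs[group_a], xs[group_b]])
    n_all = np.concatenate([ns[group_a], ns[group_b]])
    p_pooled = float(x_all.sum() / n_all.sum())
    ll0 = _bernoulli_loglik(x_all, n_all, p_pooled)

    p_group, ll1 = {}, 0.0
    for g in (group_a, group_b):
        p_g = float(xs[g].sum() / ns[g].sum())
        p_group[g] = p_g
        ll1 += _bernoulli_loglik(xs[g], ns[g], p_g)

    lam = max(0.0, -2.0 * (ll0 - ll1))
    return LRTResult(
        groups=(group_a, group_b),
        p_pooled=p_pooled,
        p_group=p_group,
        loglik_null=ll0,
        loglik_alt=ll1,
        lam=lam,
        p_value=chisq1_pvalue(lam),
    )


def chisq1_pvalue(lam: float) -> float:
    """Survival function of chi-square with one degree of freedom."""
    if lam < 0:
        raise ValueError("LRT statistic must be non-negative")
    return float(stats.chi2.sf(lam, df=1))


def genetic_load(state_counts: pd.DataFrame, groups: pd.Series | dict) -> LoadResult:
    """Deleterious-to-synonymous ratio per individual and group means.

    ``state_counts`` is the tidy frame from
    :func:`rohdel.polarize.state_counts` (sample, functional_class,
    state, count); ``groups`` maps sample -> group.  The ratio is
    computed separately for heterozygous and homozygous-derived
    genotypes; individuals with zero synonymous sites in a state are
    flagged NaN and excluded from the group mean.
    """
    if not isinstance(groups, dict):
        groups = dict(groups)
    wide = state_counts.pivot_table(
        index="sample", columns=["functional_class", "state"], values="count", fill_value=0
    )

    def ratio(sample, state):
        try:
            syn = wide.loc[sample, ("synonymous", state)]
        except KeyError:
            return np.nan
        dele = wide.loc[sample, ("deleterious", state)] if ("deleterious", state) in wide.columns else 0
        return dele / syn if syn > 0 else np.nan

    rows = [
        {
            "sample": s,
            "group": groups.get(s),
            "het_load": ratio(s, "het"),
            "hom_load": ratio(s, "hom_der"),
        }
        for s in wide.index
    ]
    per_ind = pd.DataFrame(rows)
    means = (
        per_ind.groupby("group")
        .agg(het_load=("het_load", "mean"), hom_load=("hom_load", "mean"), n=("sample", "size"))
        .reset_index()
    )
    return LoadResult(per_individual=per_ind, group_means=means)


def site_daf(derived_codes) -> np.ndarray:
    """Per-site derived allele frequency from derived-count codes.

    Sites with every genotype missing get NaN (and are skipped by
    :func:`daf_spectrum`).
    """
    codes = np.asarray(derived_codes)
    present = codes >= 0
    n_chrom = 2 * present.sum(axis=1)
    der = np.where(present, codes, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_chrom > 0, der / np.maximum(n_chrom, 1), np.nan)


def daf_spectrum(dafs) -> np.ndarray:
    """Histogram DAFs into 10 bins: [0, 0.1), ..., [0.9, 1.0].

    The last bin is closed so fixed derived sites (DAF = 1) are
    retained.  NaN frequencies (all-missing sites) are skipped.
    """
    f = np.asarray(dafs, dtype=float)
    f = f[~np.isnan(f)]
    if np.any((f < 0) | (f > 1)):
        raise ValueError("frequencies must be in [0, 1]")
    counts, _ = np.histogram(f, bins=np.linspace(0.0, 1.0, 11))
    return counts


def daf_spectra_by_class(dafs, classes) -> SFSResult:
    """DAF spectrum per functional class."""
    cls = pd.Series(list(classes))
    f = np.asarray(dafs, float)
    res = SFSResult()
    for c in pd.unique(cls.dropna()):
        res.counts[c] = daf_spectrum(f[(cls == c).to_numpy()])
    return res


def _interval_arrays(rohs: list[ROH], size_class: str):
    by_chrom: dict[str, list] = {}
    for r in rohs:
        if size_class == "any" or r.size_class == size_class:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    out = {}
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        out[chrom] = (
            np.array([s for s, _ in ivals]),
            np.array([e for _, e in ivals]),
        )
    return out


def positions_in_intervals(chroms, positions, rohs: list[ROH], size_class: str = "any") -> np.ndarray:
    """Boolean per position: lies inside an ROH of the given class.

    Positions are 0-based; intervals are half-open.  ROHs of one
    individual are disjoint, so membership reduces to a sorted search.
    """
    chroms = np.asarray(chroms)
    positions = np.asarray(positions)
    inside = np.zeros(positions.shape, dtype=bool)
    arrays = _interval_arrays(rohs, size_class)
    for chrom, (starts, ends) in arrays.items():
        m = chroms == chrom
        if not m.any():
            continue
        idx = np.searchsorted(starts, positions[m], side="right") - 1
        ok = idx >= 0
        hit = np.zeros(idx.shape, bool)
        hit[ok] = positions[m][ok] < ends[idx[ok]]
        inside[m] = hit
    return inside


def roh_enrichment(
    variants_by_individual: dict[str, pd.DataFrame],
    rohs_by_individual: dict[str, list[ROH]],
    chrom_lengths,
) -> pd.DataFrame:
    """Counts of homozygous-derived variants inside/outside ROH classes.

    ``variants_by_individual`` maps sample -> frame with columns
    ``chrom``, ``pos0`` (0-based) and ``damaging`` (bool), one row per
    homozygous-derived genotype of that individual at a passing site.
    Returns one row per individual x size class x category with
    ``count_in_roh``, ``count_outside``, ``fraction_in_roh`` and the
    genome fraction ``G``.
    """
    rows = []
    for sample, variants in variants_by_individual.items():
        rohs = rohs_by_individual.get(sample, [])
        chroms = variants["chrom"].to_numpy()
        pos = variants["pos0"].to_numpy()
        damaging = variants["damaging"].to_numpy(bool)
        for cls in ENRICHMENT_CLASSES:
            inside = positions_in_intervals(chroms, pos, rohs, cls)
            g = genome_fraction(rohs, chrom_lengths, cls)
            for category, m in (("damaging", damaging), ("nondamaging", ~damaging)):
                n_in = int((inside & m).sum())
                n_tot = int(m.sum())
                rows.append(
                    {
                        "sample": sample,
                        "size_class": cls,
                        "category": category,
                        "count_in_roh": n_in,
                        "count_outside": n_tot - n_in,
                        "fraction_in_roh": n_in / n_tot if n_tot else np.nan,
                        "G": g,
                    }
                )
    return pd.DataFrame(rows)


def enrichment_correlation(
    rows: pd.DataFrame, size_class: str, category: str
) -> tuple[float, float]:
    """Pearson correlation of fraction-in-ROH vs genome ROH fraction G.

    A positive correlation means individuals whose genomes carry more
    ROH also concentrate more of their homozygous-derived variants
    inside ROHs.  Returns ``(nan, nan)`` when fewer than three
    individuals have defined fractions or either vector is constant.
    """
    sub = rows[(rows["size_class"] == size_class) & (rows["category"] == category)]
    sub = sub.dropna(subset=["fraction_in_roh", "G"])
    if len(sub) < 3:
        return (np.nan, np.nan)
    x = sub["G"].to_numpy(float)
    y = sub["fraction_in_roh"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (np.nan, np.nan)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
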