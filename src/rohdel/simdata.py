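"""Synthetic populations with planted autozygosity and known truth.

The generator emulates the data a resequencing study of small managed
populations produces, at the level the downstream statistics consume:
polarized bi-allelic SNP genotypes with class-specific derived-allele
frequency spectra, per-sample read depths, and outgroup samples fixed
for the ancestral allele.  Autozygosity is modelled directly: each
individual receives planted identical-by-descent (IBD) tracts whose
number and length distribution are group parameters, so recently
bottlenecked groups can carry few long tracts while older small
populations carry many short ones.  Inside a tract the two alleles are
copies of one sampled haplotype (homozygous, up to a residual
heterozygosity leak); outside, genotypes are Hardy-Weinberg draws from
the site frequency.

Everything downstream is testable against the emitted truth: tract
intervals per individual, the ancestral allele and class label per
site, and per-group homozygous-derived proportions.

No linkage, recombination or selection dynamics are modelled — the
implemented statistics are functions of marginal genotype and tract
distributions only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GroupSpec:
    """Demographic parameters of one management group.

    ``roh_rate_per_mb`` is the expected number of planted IBD tracts per
    megabase per individual; tract lengths are log-normal with the given
    parameters of log-length (natural log of bp).
    """

    name: str
    n_individuals: int
    roh_rate_per_mb: float
    roh_length_log_mean: float = np.log(2e6)
    roh_length_log_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if self.roh_rate_per_mb < 0:
            raise ValueError("roh_rate_per_mb must be >= 0")
        if not np.isfinite([self.roh_length_log_mean, self.roh_length_log_sd]).all():
            raise ValueError("length distribution parameters must be finite")


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    chrom_lengths: tuple = (("chr1", 20_000_000),)
    groups: tuple = (
        GroupSpec("lf", 10, roh_rate_per_mb=0.02, roh_length_log_mean=np.log(3e5)),
        GroupSpec("nb", 10, roh_rate_per_mb=0.08, roh_length_log_mean=np.log(2.5e6)),
    )
    n_sites_per_class: dict = field(
        default_factory=lambda: {
            "synonymous": 6000,
            "tolerated": 1700,
            "deleterious": 400,
            "lof": 80,
        }
    )
    sfs_shape: dict = field(
        default_factory=lambda: {
            "synonymous": (0.5, 0.5),
            "tolerated": (0.4, 0.8),
            "deleterious": (0.2, 2.0),
            "lof": (0.2, 2.0),
        }
    )
    mean_coverage: float = 13.4
    missing_rate: float = 0.02
    outgroup_n: int = 3
    outgroup_error_rate: float = 0.0
    in_tract_het_leak: float = 0.01
    ancestral_is_ref_prob: float = 0.5
    # probability, per class, that a site is placed inside the union of
    # planted tracts rather than uniformly (models damaging variants
    # concentrating in autozygous regions)
    in_tract_placement_bias: dict = field(default_factory=dict)
    # fraction of annotation records failing each confidence filter
    contaminant_fraction: float = 0.0
    track_bin_size: int = 10_000

    def __post_init__(self) -> None:
        for p in (
            self.missing_rate,
            self.outgroup_error_rate,
            self.in_tract_het_leak,
            self.ancestral_is_ref_prob,
            self.contaminant_fraction,
            *self.in_tract_placement_bias.values(),
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.mean_coverage <= 0 or self.outgroup_n <= 0:
            raise ValueError("counts and coverage must be positive")
        if any(n < 0 for n in self.n_sites_per_class.values()):
            raise ValueError("site counts must be >= 0")
        for cls in self.n_sites_per_class:
            if cls not in self.sfs_shape:
                raise ValueError(f"no sfs_shape for class {cls!r}")
        names = [c for c, _ in self.chrom_lengths]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class TruthSet:
    planted_tracts: dict[str, list[tuple[str, int, int]]]
    ancestral_alleles: np.ndarray  # per site, the true ancestral base
    class_labels: np.ndarray
    group_hom_der_proportions: pd.DataFrame  # group, functional_class, proportion


@dataclass
class SimResult:
    config: SimConfig
    samples: list[str]
    groups: dict[str, str]  # sample -> group
    outgroups: list[str]
    sites: pd.DataFrame  # chrom, pos0, ref, alt, anc_is_ref, functional_class, daf
    genotypes: np.ndarray  # (n_sites, n_samples + n_outgroups) ALT counts, -1 missing
    depths: np.ndarray
    annotation: pd.DataFrame
    coverage: pd.DataFrame  # sample, mean_depth
    wellcovered: dict[str, dict[str, np.ndarray]]  # sample -> chrom -> per-bin counts
    truth: TruthSet

    @property
    def all_samples(self) -> list[str]:
        return self.samples + self.outgroups


def sample_site_frequencies(config: SimConfig, functional_class: str, rng) -> np.ndarray:
    """Draw derived-allele frequencies for one class from its Beta shape.

    Frequencies are truncated into the open interval (0, 1) so every
    site segregates in the infinite source population.
    """
    if functional_class not in config.n_sites_per_class:
        raise ValueError(f"unknown functional class {functional_class!r}")
    n = config.n_sites_per_class[functional_class]
    if n == 0:
        return np.empty(0)
    a, b = config.sfs_shape[functional_class]
    f = rng.beta(a, b, size=n)
    eps = 1e-9
    return np.clip(f, eps, 1 - eps)


def plant_roh_tracts(group: GroupSpec, chrom_lengths, rng) -> list[tuple[str, int, int]]:
    """Plant IBD tracts for one individual.

    Tract count per chromosome is Poisson(rate x length); starts are
    uniform; lengths log-normal.  Tracts are clipped to chromosome
    bounds and overlapping tracts merged.
    """
    tracts: list[tuple[str, int, int]] = []
    for chrom, length in chrom_lengths:
        n = rng.poisson(group.roh_rate_per_mb * length / 1e6)
        if n == 0:
            continue
        starts = rng.integers(0, length, size=n)
        sizes = rng.lognormal(group.roh_length_log_mean, group.roh_length_log_sd, size=n)
        ivals = sorted(
            (int(s), int(min(length, s + max(1, round(sz)))))
            for s, sz in zip(starts, sizes)
        )
        merged = [ivals[0]]
        for s, e in ivals[1:]:
            ps, pe = merged[-1]
            if s <= pe:
                merged[-1] = (ps, max(pe, e))
            else:
                merged.append((s, e))
        tracts.extend((chrom, s, e) for s, e in merged)
    return tracts


def _place_sites(config: SimConfig, tract_union, rng) -> pd.DataFrame:
    """Choose distinct (chrom, pos) for every site; biased classes land
    inside the planted-tract union with the configured probability."""
    names = [c for c, _ in config.chrom_lengths]
    lengths = np.array([l for _, l in config.chrom_lengths], dtype=float)
    probs = lengths / lengths.sum()

    rows = []
    for cls, n in config.n_sites_per_class.items():
        bias = config.in_tract_placement_bias.get(cls, 0.0)
        in_tract = rng.random(n) < bias if bias > 0 else np.zeros(n, bool)
        chrom_idx = rng.choice(len(names), size=n, p=probs)
        pos = (rng.random(n) * lengths[chrom_idx]).astype(np.int64)
        n_bias = int(in_tract.sum())
        if n_bias and tract_union:
            t_chrom = np.array([c for c, _, _ in tract_union])
            t_start = np.array([s for _, s, _ in tract_union])
            t_len = np.array([e - s for _, s, e in tract_union], dtype=float)
            pick = rng.choice(len(tract_union), size=n_bias, p=t_len / t_len.sum())
            off = (rng.random(n_bias) * t_len[pick]).astype(np.int64)
            bpos = t_start[pick] + off
            bchrom = np.array([names.index(c) for c in t_chrom[pick]])
            chrom_idx[in_tract] = bchrom
            pos[in_tract] = bpos
        for ci, p in zip(chrom_idx, pos):
            rows.append((names[ci], int(p), cls))

    df = pd.DataFrame(rows, columns=["chrom", "pos0", "functional_class"])
    # resolve position collisions by redrawing uniformly on the chromosome
    for _ in range(100):
        dup = df.duplicated(subset=["chrom", "pos0"], keep="first")
        if not dup.any():
            break
        idx = df.index[dup]
        chlen = dict(config.chrom_lengths)
        df.loc[idx, "pos0"] = [int(rng.integers(0, chlen[c])) for c in df.loc[idx, "chrom"]]
    order = {c: i for i, (c, _) in enumerate(config.chrom_lengths)}
    df["corder"] = df["chrom"].map(order)
    df = df.sort_values(["corder", "pos0"]).drop(columns="corder").reset_index(drop=True)
    return df


def _merge_union(tracts):
    by_chrom: dict[str, list] = {}
    for chrom, s, e in tracts:
        by_chrom.setdefault(chrom, []).append((s, e))
    union = []
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        cur = list(ivals[0])
        for s, e in ivals[1:]:
            if s <= cur[1]:
                cur[1] = max(cur[1], e)
            else:
                union.append((chrom, cur[0], cur[1]))
                cur = [s, e]
        union.append((chrom, cur[0], cur[1]))
    return union


def _in_tracts_mask(sites: pd.DataFrame, tracts) -> np.ndarray:
    mask = np.zeros(len(sites), dtype=bool)
    chroms = sites["chrom"].to_numpy()
    pos = sites["pos0"].to_numpy()
    by_chrom: dict[str, list] = {}
    for chrom, s, e in tracts:
        by_chrom.setdefault(chrom, []).append((s, e))
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        starts = np.array([s for s, _ in ivals])
        ends = np.array([e for _, e in ivals])
        m = chroms == chrom
        idx = np.searchsorted(starts, pos[m], side="right") - 1
        ok = idx >= 0
        hit = np.zeros(idx.shape, bool)
        hit[ok] = pos[m][ok] < ends[idx[ok]]
        mask[m] = hit
    return mask


def depth_pass_probability(mean_coverage: float, min_depth: int = 4, max_depth_factor: float = 2.0) -> float:
    """P(Poisson(mean) lands inside the depth-filter window)."""
    hi = np.floor(max_depth_factor * mean_coverage)
    return float(
        stats.poisson.cdf(hi, mean_coverage) - stats.poisson.cdf(min_depth - 1, mean_coverage)
    )


def simulate_population(config: SimConfig) -> SimResult:
    """Run the full generator; identical config gives identical output."""
    rng = np.random.default_rng(config.seed)

    samples, group_of, tracts_by_ind = [], {}, {}
    for grp in config.groups:
        for i in range(grp.n_individuals):
            name = f"{grp.name}{i + 1:02d}"
            samples.append(name)
            group_of[name] = grp.name
            tracts_by_ind[name] = plant_roh_tracts(grp, config.chrom_lengths, rng)
    outgroups = [f"og{i + 1:02d}" for i in range(config.outgroup_n)]

    all_tracts = [t for ts in tracts_by_ind.values() for t in ts]
    tract_union = _merge_union(all_tracts) if all_tracts else []
    sites = _place_sites(config, tract_union, rng)
    n_sites = len(sites)

    # derived-allele frequencies per class, assigned site-wise
    daf = np.empty(n_sites)
    for cls in config.n_sites_per_class:
        m = (sites["functional_class"] == cls).to_numpy()
        freqs = sample_site_frequencies(config, cls, rng)
        daf[m] = freqs[: m.sum()]
    sites["daf"] = daf

    anc_is_ref = rng.random(n_sites) < config.ancestral_is_ref_prob
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    sites["ref"] = _BASES[ref_idx]
    sites["alt"] = _BASES[alt_idx]
    sites["anc_is_ref"] = anc_is_ref

    # genotypes on the derived-count scale first
    n_total = len(samples) + len(outgroups)
    der = np.empty((n_sites, n_total), dtype=np.int8)
    for j, s in enumerate(samples):
        hw = rng.binomial(2, daf).astype(np.int8)
        in_tract = _in_tracts_mask(sites, tracts_by_ind[s])
        k = int(in_tract.sum())
        if k:
            hap = (rng.random(k) < daf[in_tract]).astype(np.int8)
            g = 2 * hap
            leak = rng.random(k) < config.in_tract_het_leak
            g[leak] = 1
            hw[in_tract] = g
        der[:, j] = hw
    for j in range(len(outgroups)):
        col = np.zeros(n_sites, dtype=np.int8)
        err = rng.random(n_sites) < config.outgroup_error_rate
        if err.any():
            col[err] = rng.integers(1, 3, size=int(err.sum()), dtype=np.int8)
        der[:, len(samples) + j] = col

    # true per-group homozygous-derived proportions, before missingness
    rows = []
    cls_arr = sites["functional_class"].to_numpy()
    for grp in config.groups:
        cols = [j for j, s in enumerate(samples) if group_of[s] == grp.name]
        for cls in config.n_sites_per_class:
            m = cls_arr == cls
            block = der[np.ix_(m, cols)]
            rows.append(
                {
                    "group": grp.name,
                    "functional_class": cls,
                    "proportion": float((block == 2).mean()) if block.size else np.nan,
                }
            )
    truth_props = pd.DataFrame(rows)

    # ALT-count scale: flip where the ancestral allele is ALT
    gt = np.where(anc_is_ref[:, None], der, 2 - der).astype(np.int8)

    depths = rng.poisson(config.mean_coverage, size=(n_sites, n_total)).astype(np.int32)
    missing = rng.random((n_sites, n_total)) < config.missing_rate
    gt[missing] = -1

    annotation = _build_annotation(sites, config, rng)
    coverage = pd.DataFrame(
        {"sample": samples + outgroups, "mean_depth": config.mean_coverage}
    )

    p_pass = depth_pass_probability(config.mean_coverage)
    wellcovered: dict[str, dict[str, np.ndarray]] = {}
    for s in samples + outgroups:
        wellcovered[s] = {}
        for chrom, length in config.chrom_lengths:
            n_bins = -(-length // config.track_bin_size)
            spans = np.full(n_bins, config.track_bin_size, dtype=np.int64)
            spans[-1] = length - (n_bins - 1) * config.track_bin_size
            wellcovered[s][chrom] = rng.binomial(spans, p_pass).astype(np.int64)

    truth = TruthSet(
        planted_tracts=tracts_by_ind,
        ancestral_alleles=np.where(anc_is_ref, sites["ref"], sites["alt"]),
        class_labels=cls_arr,
        group_hom_der_proportions=truth_props,
    )
    return SimResult(
        config=config,
        samples=samples,
        groups=group_of,
        outgroups=outgroups,
        sites=sites,
        genotypes=gt,
        depths=depths,
        annotation=annotation,
        coverage=coverage,
        wellcovered=wellcovered,
        truth=truth,
    )


def _build_annotation(sites: pd.DataFrame, config: SimConfig, rng) -> pd.DataFrame:
    n = len(sites)
    cls = sites["functional_class"].to_numpy()
    consequence = np.full(n, "intergenic_variant", dtype=object)
    consequence[cls == "synonymous"] = "synonymous_variant"
    consequence[(cls == "tolerated") | (cls == "deleterious")] = "missense_variant"
    consequence[cls == "lof"] = "stop_gained"

    sift = np.full(n, np.nan)
    m = cls == "deleterious"
    sift[m] = rng.uniform(0.0, 0.05, size=int(m.sum()))
    m = cls == "tolerated"
    sift[m] = rng.uniform(0.05, 1.0, size=int(m.sum()))

    gerp = rng.uniform(-2.0, 1.0, size=n)
    m = cls == "deleterious"
    gerp[m] = rng.uniform(1.5, 6.0, size=int(m.sum()))

    orth = np.ones(n, dtype=bool)
    rna = rng.integers(200, 2000, size=n)
    if config.contaminant_fraction > 0:
        orth[rng.random(n) < config.contaminant_fraction] = False
        low = rng.random(n) < config.contaminant_fraction
        rna[low] = rng.integers(0, 200, size=int(low.sum()))

    return pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "pos": sites["pos0"] + 1,
            "ref": sites["ref"],
            "alt": sites["alt"],
            "gene": [f"gene{i // 20:05d}" for i in range(n)],
            "consequence": consequence,
            "sift": sift,
            "gerp": gerp,
            "orth_1to1": orth,
            "rna_cov": rna,
        }
    )
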