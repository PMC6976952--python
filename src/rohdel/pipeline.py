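"""End-to-end runner: windows -> ROHs -> polarization -> burden stats.

The pipeline mirrors the analysis order of a resequencing study of
bottlenecked populations: per-sample coverage-corrected heterozygosity
tracks, ROH calling against each individual's own genome-wide mean,
outgroup-based polarization with functional-class filtering, and the
group-level burden statistics.  Every stage logs row counts into a run
manifest so reruns on real data are auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import burden, hetwin, io, polarize, rohfind

logger = logging.getLogger("rohdel")


@dataclass
class PipelineConfig:
    vcf: str
    annotation: str
    coverage: str
    groups: str
    outgroups: str
    outdir: str
    wellcovered: str | None = None
    chrom_lengths: list = field(default_factory=list)  # [(name, length)]
    het: hetwin.HetParams = field(default_factory=hetwin.HetParams)
    roh: rohfind.ROHParams = field(default_factory=rohfind.ROHParams)
    sift_deleterious: float = 0.05
    gerp_constrained: float = 1.0
    min_rna_cov: float = 200.0
    # sample filters for the burden stage
    min_mean_coverage: float = 10.0
    max_missing_fraction: float = 0.10
    lrt_groups: tuple[str, str] = ("lf", "nb")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        het_kw = raw.pop("het", {})
        roh_kw = raw.pop("roh", {})
        raw["chrom_lengths"] = [tuple(x) for x in raw.get("chrom_lengths", [])]
        if "lrt_groups" in raw:
            raw["lrt_groups"] = tuple(raw["lrt_groups"])
        cfg = cls(**raw)
        cfg.het = hetwin.HetParams(**het_kw)
        cfg.roh = rohfind.ROHParams(**roh_kw)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["chrom_lengths"] = [list(x) for x in self.chrom_lengths]
        d["lrt_groups"] = list(self.lrt_groups)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def validate(self) -> None:
        for name in ("vcf", "annotation", "coverage", "groups", "outgroups"):
            path = getattr(self, name)
            if not os.path.exists(path):
                raise FileNotFoundError(f"{name} file not found: {path}")
        if not 0 <= self.sift_deleterious <= 1:
            raise ValueError("sift_deleterious must be in [0, 1]")
        if not self.chrom_lengths:
            raise ValueError("chrom_lengths must be provided")


@dataclass
class RunManifest:
    config_hash: str
    version: str
    counts: dict = field(default_factory=dict)
    stages_completed: list = field(default_factory=list)
    started: float = 0.0
    finished: float = 0.0
    error: str | None = None

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _sample_windows(table, sample_idx, sample, mean_cov, cfg, wellcov):
    frames = []
    for chrom, length in cfg.chrom_lengths:
        m = table.chrom == chrom
        gt = table.genotypes[m, sample_idx]
        dp = (
            table.depths[m, sample_idx]
            if table.depths is not None
            else np.full(int(m.sum()), 10**6)
        )
        track = wellcov.get(sample, {}).get(chrom) if wellcov else None
        frames.append(
            hetwin.window_heterozygosity(
                table.pos0[m],
                gt == 1,
                dp,
                mean_cov,
                chrom,
                length,
                cfg.het,
                wellcovered=track,
            )
        )
    return pd.concat(frames, ignore_index=True)


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute all stages; outputs and the manifest land in ``cfg.outdir``."""
    from . import __version__

    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest = RunManifest(config_hash=cfg.config_hash(), version=__version__, started=time.time())
    manifest_path = os.path.join(cfg.outdir, "manifest.json")
    try:
        _run_stages(cfg, manifest)
    except Exception as err:  # partial manifest still written
        manifest.error = f"{type(err).__name__}: {err}"
        manifest.finished = time.time()
        manifest.write(manifest_path)
        raise
    manifest.finished = time.time()
    manifest.write(manifest_path)
    return manifest


def _run_stages(cfg: PipelineConfig, manifest: RunManifest) -> None:
    groups = io.read_groups_tsv(cfg.groups)
    coverage = io.read_coverage_tsv(cfg.coverage)
    outgroup_names = io.read_outgroups(cfg.outgroups)
    table = io.read_vcf_sites(cfg.vcf)
    wellcov = io.read_wellcovered_track(cfg.wellcovered) if cfg.wellcovered else None
    if table.depths is None:
        logger.warning("FORMAT/DP absent: depth filtering disabled")
    manifest.counts["sites_read"] = table.n_sites
    manifest.counts.update({f"skipped_{k}": v for k, v in table.skipped.items()})

    focal = [s for s in table.samples if s not in outgroup_names]
    focal_idx = [table.samples.index(s) for s in focal]
    og_idx = [table.samples.index(s) for s in outgroup_names]
    if not og_idx:
        raise ValueError("no outgroup samples found in VCF")

    # stage 1-2: heterozygosity windows and ROH calling, per sample
    windows_dir = os.path.join(cfg.outdir, "windows")
    roh_dir = os.path.join(cfg.outdir, "roh")
    os.makedirs(windows_dir, exist_ok=True)
    os.makedirs(roh_dir, exist_ok=True)
    rohs_by_sample: dict[str, list] = {}
    summary_rows = []
    for s, j in zip(focal, focal_idx):
        win = _sample_windows(table, j, s, coverage[s], cfg, wellcov)
        io.write_windows_tsv(win, os.path.join(windows_dir, f"{s}.windows.tsv"))
        gm = hetwin.genome_mean_het(win)
        rohs = rohfind.detect_roh(win, gm, cfg.roh)
        rohs_by_sample[s] = rohs
        io.write_roh_bed(rohs, os.path.join(roh_dir, f"{s}.roh.bed"))
        summ = rohfind.roh_summary(rohs, cfg.chrom_lengths)
        summ.insert(0, "sample", s)
        summ["genome_mean_het"] = gm
        summary_rows.append(summ)
    roh_summary = pd.concat(summary_rows, ignore_index=True)
    roh_summary.to_csv(os.path.join(cfg.outdir, "roh_summary.tsv"), sep="\t", index=False)
    manifest.counts["rohs_called"] = int(sum(len(r) for r in rohs_by_sample.values()))
    manifest.stages_completed += ["hetwin", "rohfind"]

    # stage 3: polarization + functional classification
    polarizable, anc_is_ref = polarize.infer_ancestral_sites(table.genotypes[:, og_idx])
    manifest.counts["polarizable_sites"] = int(polarizable.sum())

    ann = pd.read_csv(cfg.annotation, sep="\t")
    ann = polarize.classify_table(
        ann, cfg.sift_deleterious, cfg.gerp_constrained, cfg.min_rna_cov
    )
    key = pd.DataFrame({"chrom": table.chrom, "pos": table.pos0 + 1})
    merged = key.merge(ann, on=["chrom", "pos"], how="left")
    has_ann = merged["functional_class"].notna().to_numpy()
    passes = merged["passes_filters"].fillna(False).to_numpy(bool)
    keep = polarizable & has_ann & passes
    manifest.counts["sites_passing_filters"] = int(keep.sum())

    focal_gt = table.genotypes[:, focal_idx]
    if table.depths is not None:
        # genotypes failing the per-sample depth filter count as missing
        dp = table.depths[:, focal_idx]
        for k, s in enumerate(focal):
            bad = ~hetwin.depth_filter(dp[:, k], coverage[s], cfg.het)
            focal_gt = focal_gt.copy() if k == 0 else focal_gt
            focal_gt[bad, k] = -1
    codes = polarize.polarize_genotypes(focal_gt, anc_is_ref)

    site_out = pd.DataFrame(
        {
            "chrom": table.chrom,
            "pos": table.pos0 + 1,
            "ref": table.ref,
            "alt": table.alt,
            "polarizable": polarizable,
            "ancestral": np.where(anc_is_ref, table.ref, table.alt),
            "functional_class": merged["functional_class"],
            "damaging": merged["damaging"].fillna(False),
            "passes_filters": passes,
        }
    )
    site_out.loc[~polarizable, "ancestral"] = "."
    site_out.to_csv(os.path.join(cfg.outdir, "polarized_sites.tsv"), sep="\t", index=False)

    counts_df = polarize.state_counts(
        codes, focal, merged["functional_class"], keep_mask=keep
    )
    counts_df.to_csv(os.path.join(cfg.outdir, "state_counts.tsv"), sep="\t", index=False)
    manifest.stages_completed += ["polarize", "classify"]

    # stage 4: burden statistics over samples passing the coverage filters
    missing_frac = (table.genotypes[:, focal_idx] == -1).mean(axis=0)
    analysis = [
        s
        for s, mf in zip(focal, missing_frac)
        if coverage[s] >= cfg.min_mean_coverage and mf <= cfg.max_missing_fraction
    ]
    manifest.counts["analysis_samples"] = len(analysis)
    a_idx = [focal.index(s) for s in analysis]

    daf = burden.site_daf(codes[:, a_idx])
    segregating = keep & (daf > 0) & ~np.isnan(daf)
    lrt_rows = []
    g_a, g_b = cfg.lrt_groups
    for cls in pd.unique(merged.loc[keep, "functional_class"].dropna()):
        m = segregating & (daf < 1) & (merged["functional_class"] == cls).to_numpy()
        sub = codes[np.ix_(m, a_idx)]
        cnt = pd.DataFrame(
            {
                "sample": analysis,
                "group": [groups[s] for s in analysis],
                "x": (sub == 2).sum(axis=0),
                "n": (sub >= 0).sum(axis=0),
            }
        )
        try:
            res = burden.lrt_homozygosity(cnt, g_a, g_b)
        except ValueError as err:
            logger.warning("LRT skipped for %s: %s", cls, err)
            continue
        lrt_rows.append(
            {
                "functional_class": cls,
                "p_pooled": res.p_pooled,
                f"p_{g_a}": res.p_group[g_a],
                f"p_{g_b}": res.p_group[g_b],
                "loglik_null": res.loglik_null,
                "loglik_alt": res.loglik_alt,
                "lambda": res.lam,
                "p_value": res.p_value,
            }
        )
    pd.DataFrame(lrt_rows).to_csv(os.path.join(cfg.outdir, "lrt.tsv"), sep="\t", index=False)

    sc_analysis = polarize.state_counts(
        codes[:, a_idx], analysis, merged["functional_class"], keep_mask=keep
    )
    load = burden.genetic_load(sc_analysis, groups)
    load.per_individual.to_csv(os.path.join(cfg.outdir, "load_individual.tsv"), sep="\t", index=False)
    load.group_means.to_csv(os.path.join(cfg.outdir, "load_groups.tsv"), sep="\t", index=False)

    sfs = burden.daf_spectra_by_class(
        daf[segregating], merged.loc[segregating, "functional_class"]
    )
    sfs_rows = [
        {"functional_class": cls, **{f"bin{k}": int(c) for k, c in enumerate(counts)}}
        for cls, counts in sfs.counts.items()
    ]
    pd.DataFrame(sfs_rows).to_csv(os.path.join(cfg.outdir, "sfs.tsv"), sep="\t", index=False)

    variants_by_ind = {}
    for s in analysis:
        k = focal.index(s)
        m = keep & (codes[:, k] == 2)
        variants_by_ind[s] = pd.DataFrame(
            {
                "chrom": table.chrom[m],
                "pos0": table.pos0[m],
                "damaging": merged.loc[m, "damaging"].fillna(False).to_numpy(bool),
            }
        )
    enrich = burden.roh_enrichment(
        variants_by_ind,
        {s: rohs_by_sample[s] for s in analysis},
        cfg.chrom_lengths,
    )
    enrich.to_csv(os.path.join(cfg.outdir, "enrichment.tsv"), sep="\t", index=False)
    manifest.stages_completed += ["burden"]
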