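"""File formats: VCF 4.2, BED, and the pipeline's TSV sidecars.

Internal coordinates are 0-based half-open everywhere; VCF positions
(1-based) and BED lines are converted at this boundary.  Genotypes are
carried as ALT-allele counts (0/1/2) with -1 for missing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from cyvcf2 import VCF

from .rohfind import ROH, classify_roh
from .simdata import SimResult

# cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
_GT_TYPE_TO_CODE = np.array([0, 1, -1, 2], dtype=np.int8)


@dataclass
class SiteTable:
    """Bi-allelic SNP records loaded from a VCF, column-per-sample."""

    samples: list[str]
    chrom: np.ndarray
    pos0: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray  # (n_sites, n_samples) ALT counts, -1 missing
    depths: np.ndarray | None  # None when FORMAT/DP is absent
    skipped: dict[str, int] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.pos0)


def read_vcf_sites(path, samples=None) -> SiteTable:
    """Stream a VCF into a :class:`SiteTable` of bi-allelic SNPs.

    Multi-allelic and non-SNP records are counted and skipped.  When
    FORMAT/DP is absent the table's ``depths`` is None and downstream
    depth filtering is disabled (callers should warn loudly).
    """
    vcf = VCF(str(path), samples=list(samples) if samples is not None else None)
    names = list(vcf.samples)
    chroms, pos0, refs, alts, gts, dps = [], [], [], [], [], []
    skipped = {"multiallelic": 0, "indel_or_other": 0}
    has_dp = True
    for v in vcf:
        if len(v.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        if not v.is_snp:
            skipped["indel_or_other"] += 1
            continue
        chroms.append(v.CHROM)
        pos0.append(v.POS - 1)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        gts.append(_GT_TYPE_TO_CODE[v.gt_types])
        if has_dp:
            try:
                dp = v.format("DP")
            except KeyError:
                dp = None
            if dp is None:
                has_dp = False
            else:
                dps.append(dp[:, 0])
    vcf.close()
    n = len(pos0)
    return SiteTable(
        samples=names,
        chrom=np.array(chroms, dtype=object),
        pos0=np.array(pos0, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        genotypes=np.vstack(gts) if n else np.empty((0, len(names)), np.int8),
        depths=np.vstack(dps).astype(np.int32) if has_dp and n else None,
        skipped=skipped,
    )


def write_vcf(sim: SimResult, path) -> None:
    """Serialize a simulated population as a multi-sample VCF 4.2."""
    header = pysam.VariantHeader()
    for chrom, length in sim.config.chrom_lengths:
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    names = sim.all_samples
    for s in names:
        header.add_sample(s)
    gt_pairs = {0: (0, 0), 1: (0, 1), 2: (1, 1), -1: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in range(len(sim.sites)):
            row = sim.sites.iloc[i]
            rec = out.new_record(
                contig=row["chrom"],
                start=int(row["pos0"]),
                alleles=(row["ref"], row["alt"]),
            )
            for j, s in enumerate(names):
                rec.samples[s]["GT"] = gt_pairs[int(sim.genotypes[i, j])]
                rec.samples[s]["DP"] = int(sim.depths[i, j])
            out.write(rec)


def write_roh_bed(rohs: list[ROH], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tlength\tcovered_length\tmean_het\tsize_class\n")
        for r in sorted(rohs, key=lambda r: (r.chrom, r.start)):
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.length}\t{r.covered_length}"
                f"\t{r.mean_het:.6g}\t{r.size_class}\n"
            )


def read_roh_bed(path) -> list[ROH]:
    """Read a per-sample ROH BED; overlapping intervals are rejected."""
    rohs: list[ROH] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 tab-separated fields")
            try:
                chrom = parts[0]
                start, end, length, covered = map(int, parts[1:5])
                mean_het = float(parts[5])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: malformed ROH line") from err
            rohs.append(ROH(chrom, start, end, length, covered, mean_het, parts[6]))
    by_chrom: dict[str, list] = {}
    for r in rohs:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    for chrom, ivals in by_chrom.items():
        ivals.sort()
        for (s1, e1), (s2, _) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValueError(f"{path}: overlapping intervals on {chrom}")
    return rohs


def write_windows_tsv(windows: pd.DataFrame, path) -> None:
    windows.to_csv(path, sep="\t", index=False)


def read_windows_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_wellcovered_track(sim: SimResult, path) -> None:
    """BED-graph-like per-bin counts of well-covered sites, all samples."""
    bs = sim.config.track_bin_size
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tstart\tend\tn_wellcovered\n")
        for s, per_chrom in sim.wellcovered.items():
            for chrom, counts in per_chrom.items():
                length = dict(sim.config.chrom_lengths)[chrom]
                for b, c in enumerate(counts):
                    fh.write(f"{s}\t{chrom}\t{b * bs}\t{min((b + 1) * bs, length)}\t{c}\n")


def read_wellcovered_track(path) -> dict[str, dict[str, np.ndarray]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, np.ndarray]] = {}
    for (s, chrom), grp in df.groupby(["sample", "chrom"]):
        out.setdefault(s, {})[chrom] = grp.sort_values("start")["n_wellcovered"].to_numpy()
    return out


def write_sim(sim: SimResult, outdir) -> dict[str, str]:
    """Write the full simulated data set plus truth files.

    Emits: genotypes VCF, annotation/coverage/group TSVs, the outgroup
    sample list, per-bin well-covered track, per-individual truth BEDs
    and a site-truth TSV.  Returns the mapping of artefact name to path.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "genotypes.vcf"),
        "annotation": os.path.join(outdir, "annotation.tsv"),
        "coverage": os.path.join(outdir, "coverage.tsv"),
        "groups": os.path.join(outdir, "groups.tsv"),
        "outgroups": os.path.join(outdir, "outgroups.txt"),
        "wellcovered": os.path.join(outdir, "wellcovered.tsv"),
        "truth_sites": os.path.join(outdir, "truth_sites.tsv"),
        "truth_dir": os.path.join(outdir, "truth_tracts"),
    }
    write_vcf(sim, paths["vcf"])
    sim.annotation.to_csv(paths["annotation"], sep="\t", index=False)
    sim.coverage.to_csv(paths["coverage"], sep="\t", index=False)
    pd.DataFrame(
        {"sample": sim.samples, "group": [sim.groups[s] for s in sim.samples]}
    ).to_csv(paths["groups"], sep="\t", index=False)
    with open(paths["outgroups"], "w") as fh:
        fh.writelines(f"{s}\n" for s in sim.outgroups)
    write_wellcovered_track(sim, paths["wellcovered"])
    truth_sites = sim.sites[["chrom", "pos0", "functional_class", "daf"]].copy()
    truth_sites["ancestral"] = sim.truth.ancestral_alleles
    truth_sites.to_csv(paths["truth_sites"], sep="\t", index=False)
    os.makedirs(paths["truth_dir"], exist_ok=True)
    for s, tracts in sim.truth.planted_tracts.items():
        with open(os.path.join(paths["truth_dir"], f"{s}.bed"), "w") as fh:
            for chrom, a, b in sorted(tracts):
                fh.write(f"{chrom}\t{a}\t{b}\n")
    return paths


def read_groups_tsv(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample"], df["group"]))


def read_coverage_tsv(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample"], df["mean_depth"]))


def read_outgroups(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_truth_bed(path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, a, b = line.split()[:3]
            out.append((chrom, int(a), int(b)))
    return out
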