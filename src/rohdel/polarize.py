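"""Ancestral/derived polarization and functional-class filtering.

Calling genotypes against a reference genome biases counts of
non-reference alleles, so variants are polarized into ancestral and
derived states instead: the ancestral allele at a site is the one fixed
homozygous in a panel of outgroup (wild) samples, and each focal
genotype becomes homozygous-ancestral, heterozygous or
homozygous-derived.  A site is polarizable only when every outgroup
sample is homozygous for the same allele; missing or heterozygous
outgroup genotypes break unanimity.

Coding variants are classified from their predicted consequence and
SIFT score (synonymous / tolerated / deleterious / loss-of-function),
with an extra high-confidence tier requiring evolutionary constraint
(GERP) and confidence filters on orthology and RNA-seq expression
support.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

# diploid genotypes as ALT-allele counts; -1 = missing (VCF ./.)
MISSING_CODE = -1

LOF_CONSEQUENCES = frozenset(
    {"stop_gained", "frameshift_variant", "stop_lost", "start_lost"}
)
NONSYN_CONSEQUENCES = frozenset({"missense_variant"})
SYN_CONSEQUENCES = frozenset({"synonymous_variant"})

FUNCTIONAL_CLASSES = ("synonymous", "tolerated", "deleterious", "lof")
DAMAGING_CLASSES = frozenset({"deleterious", "lof"})


class GenotypeState(IntEnum):
    MISSING = -1
    HOM_ANC = 0
    HET = 1
    HOM_DER = 2


@dataclass(frozen=True)
class PolarizedSite:
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    ancestral: str | None
    derived: str | None
    polarizable: bool


@dataclass(frozen=True)
class ClassifiedVariant:
    functional_class: str | None
    sift: float | None
    gerp: float | None
    orth_1to1: bool
    rna_cov: float
    high_confidence_deleterious: bool
    damaging: bool
    passes_filters: bool


def infer_ancestral(
    chrom: str, pos: int, ref: str, alt: str, outgroup_gts
) -> PolarizedSite:
    """Polarize one site from outgroup genotypes (ALT-count codes).

    The site is polarizable iff all outgroups are present and homozygous
    for the same allele (all ``0`` -> ancestral is REF, all ``2`` ->
    ancestral is ALT).
    """
    gts = list(outgroup_gts)
    if not gts:
        raise ValueError("at least one outgroup genotype required")
    if all(g == 0 for g in gts):
        anc, der = ref, alt
    elif all(g == 2 for g in gts):
        anc, der = alt, ref
    else:
        return PolarizedSite(chrom, pos, ref, alt, None, None, False)
    return PolarizedSite(chrom, pos, ref, alt, anc, der, True)


def infer_ancestral_sites(outgroup_gt_matrix) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized polarization over sites.

    ``outgroup_gt_matrix`` is (n_sites, n_outgroups) of ALT-count codes.
    Returns ``(polarizable, anc_is_ref)`` boolean arrays; ``anc_is_ref``
    is meaningful only where ``polarizable``.
    """
    g = np.asarray(outgroup_gt_matrix)
    all_ref = np.all(g == 0, axis=1)
    all_alt = np.all(g == 2, axis=1)
    return all_ref | all_alt, all_ref


def polarize_genotype(gt_code: int, site: PolarizedSite) -> GenotypeState:
    """Map one diploid genotype (ALT-count code) onto the derived scale."""
    if not site.polarizable:
        raise ValueError("cannot polarize genotypes at a non-polarizable site")
    if gt_code == MISSING_CODE:
        return GenotypeState.MISSING
    if gt_code not in (0, 1, 2):
        raise ValueError(f"invalid genotype code {gt_code!r}")
    der_count = gt_code if site.ancestral == site.ref else 2 - gt_code
    return GenotypeState(der_count)


def polarize_genotypes(gt_matrix, anc_is_ref) -> np.ndarray:
    """Vectorized: ALT-count matrix (sites x samples) -> derived-count codes.

    Missing stays ``-1``; otherwise the code is the derived-allele count
    (0 = HOM_ANC, 1 = HET, 2 = HOM_DER).
    """
    g = np.asarray(gt_matrix)
    flip = ~np.asarray(anc_is_ref, dtype=bool)
    out = np.where(flip[:, None], 2 - g, g)
    out[g == MISSING_CODE] = MISSING_CODE
    return out


def classify_functional(
    record,
    sift_deleterious: float = 0.05,
    gerp_constrained: float = 1.0,
) -> ClassifiedVariant:
    """Classify one annotation record (mapping with ``consequence``,
    ``sift``, ``gerp``, ``orth_1to1``, ``rna_cov``).

    Loss-of-function consequences outrank the SIFT classes; missense
    records without a SIFT score are left unclassified (class ``None``)
    and excluded from class counts downstream.
    """
    cons = record["consequence"]
    sift = record.get("sift") if hasattr(record, "get") else record["sift"]
    gerp = record.get("gerp") if hasattr(record, "get") else record["gerp"]
    sift = None if sift is None or (isinstance(sift, float) and np.isnan(sift)) else float(sift)
    gerp = None if gerp is None or (isinstance(gerp, float) and np.isnan(gerp)) else float(gerp)

    if cons in LOF_CONSEQUENCES:
        cls = "lof"
    elif cons in SYN_CONSEQUENCES:
        cls = "synonymous"
    elif cons in NONSYN_CONSEQUENCES:
        if sift is None:
            cls = None  # unscored missense
        else:
            cls = "deleterious" if sift < sift_deleterious else "tolerated"
    else:
        cls = None

    high_conf = (
        cls == "deleterious" and gerp is not None and gerp > gerp_constrained
    )
    orth = bool(record["orth_1to1"])
    rna = float(record["rna_cov"])
    return ClassifiedVariant(
        functional_class=cls,
        sift=sift,
        gerp=gerp,
        orth_1to1=orth,
        rna_cov=rna,
        high_confidence_deleterious=high_conf,
        damaging=cls in DAMAGING_CLASSES,
        passes_filters=orth and rna >= 200,
    )


def classify_table(
    annotation: pd.DataFrame,
    sift_deleterious: float = 0.05,
    gerp_constrained: float = 1.0,
    min_rna_cov: float = 200.0,
) -> pd.DataFrame:
    """Vectorized :func:`classify_functional` over an annotation table.

    Adds ``functional_class`` (pandas NA where unclassifiable),
    ``high_confidence_deleterious``, ``damaging`` and ``passes_filters``
    columns; the input frame is not modified.
    """
    df = annotation.copy()
    cons = df["consequence"]
    sift = pd.to_numeric(df["sift"], errors="coerce")
    gerp = pd.to_numeric(df["gerp"], errors="coerce")

    cls = pd.Series(pd.NA, index=df.index, dtype="object")
    cls[cons.isin(SYN_CONSEQUENCES)] = "synonymous"
    missense = cons.isin(NONSYN_CONSEQUENCES)
    cls[missense & (sift < sift_deleterious)] = "deleterious"
    cls[missense & (sift >= sift_deleterious)] = "tolerated"
    cls[cons.isin(LOF_CONSEQUENCES)] = "lof"

    df["functional_class"] = cls
    df["high_confidence_deleterious"] = (cls == "deleterious") & (gerp > gerp_constrained)
    df["damaging"] = cls.isin(DAMAGING_CLASSES)
    df["passes_filters"] = df["orth_1to1"].astype(bool) & (
        pd.to_numeric(df["rna_cov"]) >= min_rna_cov
    )
    return df


def apply_confidence_filters(classified: pd.DataFrame) -> pd.DataFrame:
    """Keep only records passing the orthology and expression filters."""
    if "passes_filters" not in classified.columns:
        raise ValueError("run classify_table first")
    return classified[classified["passes_filters"]].copy()


def state_counts(
    derived_codes,
    samples,
    classes,
    keep_mask=None,
) -> pd.DataFrame:
    """Per-sample, per-class genotype-state counts.

    Parameters
    ----------
    derived_codes
        (sites x samples) derived-count codes from
        :func:`polarize_genotypes` (non-polarizable sites must already
        be excluded or masked via ``keep_mask``).
    samples
        Sample names, one per column.
    classes
        Functional class label per site (array-like; NA excluded).
    keep_mask
        Optional boolean per site; False rows are ignored.

    Returns a tidy frame: sample, functional_class, state, count.
    """
    codes = np.asarray(derived_codes)
    cls = pd.Series(list(classes))
    keep = np.ones(codes.shape[0], dtype=bool) if keep_mask is None else np.asarray(keep_mask, bool)
    keep &= cls.notna().to_numpy()
    rows = []
    state_names = {0: "hom_anc", 1: "het", 2: "hom_der", -1: "missing"}
    for c in pd.unique(cls[keep]):
        sub = codes[keep & (cls == c).to_numpy()]
        for j, s in enumerate(samples):
            col = sub[:, j]
            for code, name in state_names.items():
                rows.append(
                    {
                        "sample": s,
                        "functional_class": c,
                        "state": name,
                        "count": int((col == code).sum()),
                    }
                )
    return pd.DataFrame(rows)
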