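"""Cohort genotypes: rare-variant prioritisation, inheritance and phasing.

Reads minimal VCF genotype calls joined with an annotation table carrying
per-database minor allele frequencies and deleteriousness scores, applies
the rare-damaging prioritisation filter (gene panel membership, maximum
MAF strictly below threshold, CADD-phred strictly above threshold, with a
pre-specified rescue list for known alleles), labels parental origin and
biallelic status including trans-phasing from clone sequencing reads, and
builds cohort-yield tables stratified by cardiac lesion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "VariantRecord",
    "VariantAnnotation",
    "GenotypeRecord",
    "InheritanceLabel",
    "CloneObservation",
    "read_genotypes",
    "read_ped",
    "filter_rare_damaging",
    "assign_inheritance",
    "phase_from_clones",
    "detect_biallelic",
    "cohort_yield_table",
]

MAF_DATABASES = ("tgp", "aric", "gnomad", "inhouse")


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    hgvs_c: str = ""
    hgvs_p: str = ""
    consequence: str = ""  # missense/nonsense/splice/indel/CNV

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("variant position must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class VariantAnnotation:
    """Per-database MAFs (absent database = not found, distinct from 0),
    CADD-phred and optional REVEL."""

    mafs: Mapping[str, float] = field(default_factory=dict)
    cadd_phred: float | None = None
    revel: float | None = None

    def max_maf(self) -> float:
        """Maximum frequency across the databases where the allele was seen;
        a variant found in no database counts as frequency 0."""
        return max(self.mafs.values(), default=0.0)


@dataclass
class GenotypeRecord:
    proband: str
    variant: VariantRecord
    annotation: VariantAnnotation = field(default_factory=VariantAnnotation)
    zygosity: str = "het"  # het | hom
    variant_reads: int | None = None
    total_reads: int | None = None

    def __post_init__(self):
        if self.zygosity not in ("het", "hom"):
            raise ValueError(f"bad zygosity {self.zygosity!r}")
        if (self.variant_reads is not None and self.total_reads is not None
                and self.variant_reads > self.total_reads):
            raise ValueError("variant reads exceed total reads")


@dataclass
class InheritanceLabel:
    origin: str = "unknown"  # maternal | paternal | de_novo | unknown
    biallelic: str = "none"  # none|homozygous|compound_het_trans|cis|unphased_pair


@dataclass(frozen=True)
class CloneObservation:
    """Allele states of one sequenced clone at two het sites of a gene."""

    clone_id: str
    locus1: str  # wt | mut
    locus2: str  # wt | mut

    def __post_init__(self):
        for state in (self.locus1, self.locus2):
            if state not in ("wt", "mut"):
                raise ValueError(f"clone allele state must be wt/mut, got {state!r}")


# ---------------------------------------------------------------------------
# input
# ---------------------------------------------------------------------------

def _read_annotation_table(path) -> dict:
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "gene"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation table lacks columns: {sorted(missing)}")
    table: dict = {}
    for row in ann.itertuples(index=False):
        key = (str(row.chrom), int(row.pos), row.ref, row.alt)
        if key in table:
            raise ValueError(f"duplicate annotation key {key}")
        mafs = {}
        for db in MAF_DATABASES:
            val = getattr(row, f"maf_{db}", None)
            if val is not None and pd.notna(val):
                mafs[db] = float(val)
        cadd = getattr(row, "cadd", None)
        revel = getattr(row, "revel", None)
        table[key] = (
            row.gene,
            VariantAnnotation(
                mafs=mafs,
                cadd_phred=float(cadd) if cadd is not None and pd.notna(cadd) else None,
                revel=float(revel) if revel is not None and pd.notna(revel) else None,
            ),
        )
    return table


def read_genotypes(vcf_path, annotation_path=None) -> list[GenotypeRecord]:
    """Join VCF genotype calls with the variant annotation table.

    Emits one record per sample carrying a non-reference genotype.
    Variants absent from the annotation table carry an empty annotation.
    """
    from cyvcf2 import VCF

    ann = _read_annotation_table(annotation_path) if annotation_path else {}
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    records: list[GenotypeRecord] = []
    for v in vcf:
        for alt in v.ALT or []:
            key = (str(v.CHROM), int(v.POS), v.REF, alt)
            gene, annotation = ann.get(key, (None, VariantAnnotation()))
            variant = VariantRecord(
                chrom=str(v.CHROM), pos=int(v.POS), ref=v.REF, alt=alt,
                gene=gene or (v.ID or "unknown"),
            )
            ad = v.format("AD")
            for si, sample in enumerate(samples):
                gt_type = v.gt_types[si]  # 0 ref, 1 het, 2 unknown, 3 hom alt
                if gt_type in (0, 2):
                    continue
                vr = tr = None
                if ad is not None:
                    counts = [int(x) for x in ad[si] if x >= 0]
                    if counts:
                        tr = sum(counts)
                        vr = counts[1] if len(counts) > 1 else None
                records.append(GenotypeRecord(
                    proband=sample,
                    variant=variant,
                    annotation=annotation,
                    zygosity="hom" if gt_type == 3 else "het",
                    variant_reads=vr,
                    total_reads=tr,
                ))
    return records


def read_ped(path) -> pd.DataFrame:
    """Read a PED pedigree (family, individual, father, mother, sex, affected)."""
    ped = pd.read_csv(
        path, sep=r"\s+", header=None, comment="#",
        names=["family", "individual", "father", "mother", "sex", "affected"],
        dtype=str,
    )
    return ped


# ---------------------------------------------------------------------------
# prioritisation filter
# ---------------------------------------------------------------------------

def filter_rare_damaging(
    records: Iterable[GenotypeRecord],
    gene_list: Iterable[str],
    maf_max: float = 1e-4,
    cadd_min: float = 15.0,
    rescue: Iterable = (),
) -> tuple[list[GenotypeRecord], list[dict]]:
    """Retain variants in panel genes with max MAF < ``maf_max`` and
    CADD-phred > ``cadd_min``.

    A variant found in no frequency database counts as frequency 0; a
    variant with no CADD score fails the CADD criterion.  Variant keys (or
    HGVS c. strings) on the ``rescue`` list bypass both score criteria but
    must still hit a panel gene.  Returns the retained records and a
    per-record decision log naming the failing criterion.
    """
    genes = set(gene_list)
    if not genes:
        raise ValueError("gene list must be non-empty")
    if maf_max <= 0 or cadd_min <= 0:
        raise ValueError("thresholds must be positive")
    rescue = set(rescue)

    retained: list[GenotypeRecord] = []
    log: list[dict] = []
    for rec in records:
        v = rec.variant
        entry = {"proband": rec.proband, "variant": v.key, "gene": v.gene,
                 "retained": False, "reason": ""}
        if v.gene not in genes:
            entry["reason"] = "gene_not_in_panel"
        elif v.key in rescue or (v.hgvs_c and v.hgvs_c in rescue):
            entry.update(retained=True, reason="rescued")
            retained.append(rec)
        elif rec.annotation.max_maf() >= maf_max:
            entry["reason"] = "frequency"
        elif rec.annotation.cadd_phred is None:
            entry["reason"] = "cadd_missing"
        elif rec.annotation.cadd_phred <= cadd_min:
            entry["reason"] = "cadd"
        else:
            entry.update(retained=True, reason="passed")
            retained.append(rec)
        log.append(entry)
    return retained, log


# ---------------------------------------------------------------------------
# inheritance and phasing
# ---------------------------------------------------------------------------

def assign_inheritance(proband_gt: str, maternal_gt: str | None,
                       paternal_gt: str | None) -> str:
    """Parental origin of a proband's variant from trio genotypes.

    Genotypes are 'ref', 'het', 'hom' or None (missing).  The variant must
    be present in the proband.  Carried by exactly one parent -> that
    parent; absent from both observed parents -> de novo; otherwise (a
    parent missing, or both parents carriers) the origin is unknown.
    """
    if proband_gt not in ("het", "hom"):
        raise ValueError("proband must carry the variant to trace its origin")
    carriers = ("het", "hom")
    mat = maternal_gt in carriers if maternal_gt in ("ref",) + carriers else None
    pat = paternal_gt in carriers if paternal_gt in ("ref",) + carriers else None
    if mat is None or pat is None:
        # a single observed carrier parent still resolves origin for a het call
        if proband_gt == "het":
            if mat:
                return "maternal"
            if pat:
                return "paternal"
        return "unknown"
    if mat and not pat:
        return "maternal"
    if pat and not mat:
        return "paternal"
    if not mat and not pat:
        return "de_novo"
    return "unknown"  # both parents carry: origin ambiguous


def phase_from_clones(observations: Sequence[CloneObservation]) -> str:
    """Phase two het variants from clone-separated allele sequencing.

    trans: some clone carries only the first variant and some clone only
    the second, with no doubly mutant clone.  cis: a doubly mutant clone
    exists and no clone carries exactly one variant.  Anything else is
    ambiguous.
    """
    if len(observations) < 2:
        raise ValueError("phasing requires at least 2 clones")
    states = {(o.locus1, o.locus2) for o in observations}
    only1 = ("mut", "wt") in states
    only2 = ("wt", "mut") in states
    both = ("mut", "mut") in states
    if only1 and only2 and not both:
        return "trans"
    if both and not only1 and not only2:
        return "cis"
    return "ambiguous"


def detect_biallelic(records: Sequence[GenotypeRecord],
                     origins: Mapping | None = None,
                     clone_phase: str | None = None) -> str:
    """Biallelic status of one proband's variant calls within a gene.

    A homozygous call dominates.  Two het calls are compound het (trans)
    when parental origins differ or clone phasing says trans; cis when the
    origins agree or phasing says cis; otherwise an unphased pair, never
    silently promoted.
    """
    genes = {r.variant.gene for r in records}
    if len(genes) > 1:
        raise ValueError(f"records span multiple genes: {sorted(genes)}")
    if not records:
        return "none"
    if any(r.zygosity == "hom" for r in records):
        return "homozygous"
    if len(records) < 2:
        return "none"
    if clone_phase == "trans":
        return "compound_het_trans"
    if clone_phase == "cis":
        return "cis"
    if origins:
        labels = {origins.get(r.variant.key, "unknown") for r in records}
        informative = labels & {"maternal", "paternal"}
        if {"maternal", "paternal"} <= labels:
            return "compound_het_trans"
        if len(informative) == 1 and "unknown" not in labels:
            return "cis"
    return "unphased_pair"


# ---------------------------------------------------------------------------
# cohort yield
# ---------------------------------------------------------------------------

def cohort_yield_table(cohort: pd.DataFrame,
                       categories: Sequence[str] | None = None) -> pd.DataFrame:
    """Carrier yield per lesion category.

    ``cohort`` needs a ``lesions`` column (iterable or ';'-separated
    string; a proband may belong to several categories) and a boolean
    ``carrier`` column.  Percent is ``100 * carriers / total`` rounded to
    one decimal; an empty category reports NA.
    """
    def as_set(x):
        if isinstance(x, str):
            return {p for p in x.split(";") if p}
        return set(x)

    lesion_sets = cohort["lesions"].map(as_set)
    carrier = cohort["carrier"].astype(bool)
    if categories is None:
        categories = sorted(set().union(*lesion_sets))
    rows = []
    for cat in categories:
        mask = lesion_sets.map(lambda s: cat in s)
        total = int(mask.sum())
        carriers = int((mask & carrier).sum())
        if carriers > total:
            raise ValueError("carrier count exceeds category total")
        percent = round(100.0 * carriers / total, 1) if total else float("nan")
        rows.append({"lesion": cat, "total": total, "carriers": carriers,
                     "percent": percent})
    return pd.DataFrame(rows)
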