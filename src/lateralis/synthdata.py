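"""Seeded generators for every input the pipeline consumes, with truth.

All generators are pure functions of their parameters and a seed, so the
whole analysis is testable without any external download:

* a fixed miniature cardiac-phenotype ontology (OBO) standing in for the
  full Human Phenotype Ontology;
* phenotype cohorts drawn from lesion archetypes (transposition spectrum,
  double-inlet/double-outlet lesions, heterotaxy with right atrial
  isomerism/asplenia, situs inversus) with per-term dropout and spurious
  additions;
* the reference 33-proband laterality cohort annotation fixture and the
  321-proband screening-cohort composition used for yield and enrichment
  calculations;
* genotype cohorts with a variant allele at control frequency ``q``
  enriched ``rho``-fold in cases, plus trios with known inheritance and
  clone observations for phasing;
* exon read-count matrices with embedded heterozygous/homozygous
  deletions under negative-binomial noise;
* deletion junction sequences with engineered microhomology or insertions
  between two repeat elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants import CloneObservation

__all__ = [
    "CohortSpec",
    "GenotypeSpec",
    "MINI_ONTOLOGY_ROOT",
    "EXCLUDED_NONSPECIFIC_TERMS",
    "BIALLELIC_PROBANDS",
    "ARCHETYPES",
    "mini_ontology_obo",
    "gen_mini_ontology",
    "archetype_table",
    "gen_phenotype_cohort",
    "write_annotations_tsv",
    "reference_cohort_annotations",
    "reference_screen_cohort",
    "reference_case_genotypes",
    "gen_genotype_cohort",
    "gen_rpkm_cohort",
    "gen_junction_case",
    "write_fasta",
]

# ---------------------------------------------------------------------------
# miniature cardiac ontology
# ---------------------------------------------------------------------------

MINI_ONTOLOGY_ROOT = "CP:0000000"

# (id, name, parents)
_MINI_TERMS = [
    ("CP:0000000", "clinical phenotype", []),
    ("CP:0000001", "abnormal cardiovascular morphology", ["CP:0000000"]),
    ("CP:0000002", "abnormal heart morphology", ["CP:0000001"]),
    ("CP:0000010", "abnormal ventricular looping", ["CP:0000002"]),
    ("CP:0000011", "L-looped ventricles", ["CP:0000010"]),
    ("CP:0000012", "indeterminate ventricular loop", ["CP:0000010"]),
    ("CP:0000015", "abnormal ventriculoarterial connection", ["CP:0000002"]),
    ("CP:0000020", "malposition of the great arteries", ["CP:0000002"]),
    ("CP:0000021", "transposition of the great arteries",
     ["CP:0000020", "CP:0000015"]),
    ("CP:0000022", "dextro-transposition of the great arteries", ["CP:0000021"]),
    ("CP:0000023", "levo-transposition of the great arteries", ["CP:0000021"]),
    ("CP:0000024", "D-malposition of the great arteries", ["CP:0000020"]),
    ("CP:0000025", "L-malposition of the great arteries", ["CP:0000020"]),
    ("CP:0000026", "anterior aorta", ["CP:0000020"]),
    ("CP:0000027", "double outlet right ventricle", ["CP:0000015"]),
    ("CP:0000030", "abnormal atrioventricular connection", ["CP:0000002"]),
    ("CP:0000031", "discordant atrioventricular connection", ["CP:0000030"]),
    ("CP:0000032", "double inlet left ventricle", ["CP:0000030"]),
    ("CP:0000038", "abnormal atrioventricular valve morphology", ["CP:0000002"]),
    ("CP:0000033", "tricuspid atresia", ["CP:0000030", "CP:0000038"]),
    ("CP:0000034", "mitral atresia", ["CP:0000030", "CP:0000038"]),
    ("CP:0000035", "straddling atrioventricular valve", ["CP:0000038"]),
    ("CP:0000040", "abnormal pulmonary valve morphology", ["CP:0000002"]),
    ("CP:0000041", "pulmonary valve stenosis", ["CP:0000040"]),
    ("CP:0000042", "pulmonary valve atresia", ["CP:0000040"]),
    ("CP:0000043", "abnormal aortic arch morphology", ["CP:0000001"]),
    ("CP:0000044", "coarctation of the aorta", ["CP:0000043"]),
    ("CP:0000045", "hypoplastic aortic arch", ["CP:0000043"]),
    ("CP:0000046", "subaortic stenosis", ["CP:0000002"]),
    ("CP:0000050", "ventricular septal defect", ["CP:0000002"]),
    ("CP:0000051", "atrial septal defect", ["CP:0000002"]),
    ("CP:0000052", "secundum atrial septal defect", ["CP:0000051"]),
    ("CP:0000053", "single ventricle", ["CP:0000002"]),
    ("CP:0000055", "dextrocardia", ["CP:0000002"]),
    ("CP:0000060", "abnormal left-right patterning", ["CP:0000000"]),
    ("CP:0000061", "situs inversus totalis", ["CP:0000060"]),
    ("CP:0000062", "heterotaxy", ["CP:0000060"]),
    ("CP:0000063", "right atrial isomerism", ["CP:0000062"]),
    ("CP:0000064", "left atrial isomerism", ["CP:0000062"]),
    ("CP:0000070", "abnormal spleen morphology", ["CP:0000000"]),
    ("CP:0000071", "asplenia", ["CP:0000070"]),
    ("CP:0000072", "polysplenia", ["CP:0000070"]),
]

#: the four nonspecific terms dropped from the primary clustering analysis
EXCLUDED_NONSPECIFIC_TERMS = (
    "CP:0000050",  # ventricular septal defect
    "CP:0000051",  # atrial septal defect
    "CP:0000052",  # secundum atrial septal defect
    "CP:0000053",  # single ventricle
)


def mini_ontology_obo() -> str:
    """OBO 1.2 text of the fixed ~40-term cardiac mini-ontology."""
    lines = ["format-version: 1.2", "ontology: cardiac-mini", ""]
    for tid, name, parents in _MINI_TERMS:
        lines.append("[Term]")
        lines.append(f"id: {tid}")
        lines.append(f"name: {name}")
        if tid == "CP:0000062":  # legacy alias for heterotaxy
            lines.append("alt_id: CP:0000999")
        for p in parents:
            lines.append(f"is_a: {p}")
        lines.append("")
    # one obsolete stanza to exercise parser behaviour
    lines += [
        "[Term]",
        "id: CP:0000090",
        "name: obsolete atrioventricular canal defect",
        "is_obsolete: true",
        "",
    ]
    return "\n".join(lines)


def gen_mini_ontology(path, seed: int | None = None) -> str:
    """Write the mini-ontology OBO file (content is fixed; seed ignored)."""
    text = mini_ontology_obo()
    with open(path, "w") as fh:
        fh.write(text)
    return str(path)


# ---------------------------------------------------------------------------
# lesion archetypes and phenotype cohorts
# ---------------------------------------------------------------------------

ARCHETYPES = {
    "simple_dtga": ["CP:0000022", "CP:0000050"],
    "dorv_dmga": ["CP:0000027", "CP:0000024", "CP:0000050"],
    "tricuspid_atresia_mga": ["CP:0000033", "CP:0000024", "CP:0000035",
                              "CP:0000044", "CP:0000050"],
    "cctga": ["CP:0000023", "CP:0000011", "CP:0000031", "CP:0000041"],
    "dilv": ["CP:0000032", "CP:0000011", "CP:0000025", "CP:0000053"],
    "other_l_looping": ["CP:0000011", "CP:0000031", "CP:0000025",
                        "CP:0000055"],
    "heterotaxy_rai": ["CP:0000062", "CP:0000063", "CP:0000071",
                       "CP:0000024", "CP:0000027", "CP:0000034",
                       "CP:0000042"],
    "situs_inversus": ["CP:0000061", "CP:0000055"],
}


def archetype_table() -> pd.DataFrame:
    """Editable archetype -> term table."""
    return pd.DataFrame(
        [(a, ";".join(ts)) for a, ts in ARCHETYPES.items()],
        columns=["archetype", "terms"],
    )


@dataclass
class CohortSpec:
    """Parameters of a synthetic phenotype cohort."""

    n_probands: int = 33
    mix: dict = field(default_factory=lambda: {
        "simple_dtga": 0.2, "cctga": 0.3, "dilv": 0.15,
        "heterotaxy_rai": 0.25, "situs_inversus": 0.1,
    })
    dropout: float = 0.15
    spurious: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.mix.values()) - 1.0) > 1e-9:
            raise ValueError("archetype proportions must sum to 1")
        for p in (self.dropout, self.spurious):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        unknown = set(self.mix) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetype id(s): {sorted(unknown)}")


def gen_phenotype_cohort(spec: CohortSpec):
    """Draw probands from archetypes with dropout and spurious terms.

    Returns ``(annotations, truth)``: raw (unclosed) per-proband term sets
    and the true archetype labels.
    """
    rng = np.random.default_rng(spec.seed)
    # largest-remainder allocation of probands to archetypes
    names = sorted(spec.mix)
    ideal = np.array([spec.mix[a] * spec.n_probands for a in names])
    counts = np.floor(ideal).astype(int)
    for i in np.argsort(ideal - counts)[::-1][: spec.n_probands - counts.sum()]:
        counts[i] += 1

    vocab = sorted(t for t, _, _ in _MINI_TERMS if t != MINI_ONTOLOGY_ROOT)
    annotations, truth = {}, {}
    idx = 0
    for arch, cnt in zip(names, counts):
        base = ARCHETYPES[arch]
        for _ in range(cnt):
            pid = f"SIM{idx:04d}"
            idx += 1
            kept = [t for t in base if rng.random() > spec.dropout]
            if not kept:  # never emit an empty phenotype
                kept = [base[rng.integers(len(base))]]
            terms = set(kept)
            if rng.random() < spec.spurious:
                terms.add(vocab[rng.integers(len(vocab))])
            annotations[pid] = terms
            truth[pid] = arch
    return annotations, truth


def write_annotations_tsv(annotations, path):
    """Write proband term sets as the 2-column (proband, term) TSV."""
    with open(path, "w") as fh:
        for pid in sorted(annotations):
            for t in sorted(annotations[pid]):
                fh.write(f"{pid}\t{t}\n")
    return str(path)


# ---------------------------------------------------------------------------
# reference cohort fixtures
# ---------------------------------------------------------------------------

#: probands carrying biallelic variation (three homozygous, one compound het)
BIALLELIC_PROBANDS = ("CVG0006", "LAT0108", "LAT0265", "LAT1763")

# per-proband raw term sets for the 33 probands of the laterality cohort,
# derived from each case's lesion class and Van Praagh segmental anatomy
_REFERENCE_COHORT = {
    "CVG0005": ARCHETYPES["cctga"] + ["CP:0000042", "CP:0000050"],
    "LAT0080": ARCHETYPES["heterotaxy_rai"] + ["CP:0000041", "CP:0000050"],
    "LAT0022": ARCHETYPES["cctga"],
    "LAT0045": ARCHETYPES["cctga"][:3],
    "LAT1696": ARCHETYPES["cctga"],
    "LAT0123": ARCHETYPES["situs_inversus"] + ["CP:0000011"],
    "LAT1246": ARCHETYPES["cctga"],
    "LAT0191": ARCHETYPES["cctga"],
    "LAT1763": ARCHETYPES["heterotaxy_rai"],
    "CVG0006": ARCHETYPES["heterotaxy_rai"],
    "LAT0108": ARCHETYPES["heterotaxy_rai"],
    "LAT0265": ARCHETYPES["heterotaxy_rai"] + ["CP:0000012"],
    "CVG0001": ARCHETYPES["cctga"],
    "LAT0040": ARCHETYPES["situs_inversus"] + ["CP:0000022"],
    "LAT0201": ARCHETYPES["other_l_looping"],
    "LAT0248": ["CP:0000062", "CP:0000063", "CP:0000071", "CP:0000024",
                "CP:0000050"],
    "LAT0658": ["CP:0000062", "CP:0000063", "CP:0000071", "CP:0000026",
                "CP:0000042"],
    "LAT0830": ["CP:0000011", "CP:0000031", "CP:0000024", "CP:0000050"],
    "LAT0858": ARCHETYPES["simple_dtga"],
    "LAT1016": ARCHETYPES["simple_dtga"],
    "LAT0909": ARCHETYPES["simple_dtga"],
    "LAT1028": ["CP:0000027", "CP:0000025", "CP:0000050"],
    "LAT1391": ARCHETYPES["simple_dtga"],
    "LAT1617": ARCHETYPES["cctga"],
    "LAT1769": ARCHETYPES["cctga"],
    "LAT0165": ["CP:0000062", "CP:0000063", "CP:0000071", "CP:0000024",
                "CP:0000041"],
    "CVG0003": ["CP:0000023", "CP:0000031", "CP:0000041"],
    "LAT0368": ARCHETYPES["cctga"],
    "LAT0457": ARCHETYPES["cctga"],
    "LAT1724": ["CP:0000062", "CP:0000063", "CP:0000071", "CP:0000027",
                "CP:0000050"],
    "LAT0048": ARCHETYPES["simple_dtga"],
    "LAT1415": ["CP:0000033", "CP:0000024", "CP:0000027", "CP:0000035",
                "CP:0000044", "CP:0000045"],
    "CVG0007": ["CP:0000027", "CP:0000024", "CP:0000046", "CP:0000045",
                "CP:0000044"],
}


def reference_cohort_annotations() -> dict:
    """Raw (unclosed) term sets for the 33-proband laterality cohort."""
    return {pid: set(terms) for pid, terms in _REFERENCE_COHORT.items()}


# lesion category labels for the 321-proband screening cohort
LESION_ALL = "All laterality CHD"
LESION_DTGA = "Simple DTGA"
LESION_DORV = "DORV with malposed GA"
LESION_CCTGA = "CCTGA"
LESION_DILV = "DILV"
LESION_DILV_D = "DILV D-looped"
LESION_DILV_L = "DILV L-looped"
LESION_OTHER_L = "Other L-looping"
LESION_ANY_L = "Any L-looping"
LESION_SI = "Situs inversus with CHD"
LESION_RAI = "Right atrial isomerism/Asplenia"
LESION_OTHER = "Unclassified"

#: (primary lesion, extra categories, total, carriers, hispanic, hispanic carriers)
_SCREEN_COMPOSITION = [
    (LESION_DTGA, (), 49, 3, 17, 1),
    (LESION_DORV, (), 26, 0, 10, 0),
    (LESION_CCTGA, (LESION_ANY_L,), 26, 4, 9, 2),
    (LESION_DILV_D, (LESION_DILV,), 11, 1, 4, 1),
    (LESION_DILV_L, (LESION_DILV, LESION_ANY_L), 22, 3, 7, 1),
    (LESION_OTHER_L, (LESION_ANY_L,), 18, 2, 5, 0),
    (LESION_SI, (), 15, 1, 3, 0),
    (LESION_RAI, (), 68, 7, 22, 5),
    (LESION_OTHER, (), 86, 0, 34, 0),
]

#: lesions most commonly associated with the gene under study
NODAL_ASSOCIATED_LESIONS = (
    LESION_DTGA, LESION_CCTGA, LESION_DILV_D, LESION_DILV_L,
    LESION_OTHER_L, LESION_RAI,
)


def reference_screen_cohort() -> pd.DataFrame:
    """Composition of the 321-proband consecutively recruited cohort.

    One row per proband with its lesion categories (a proband can count in
    several overlapping rows, e.g. CCTGA is also any-L-looping), carrier
    status for the recurrent missense allele, Hispanic ancestry flag and
    carrier zygosity.  Two of the Hispanic carriers in the right-atrial
    isomerism group are homozygous, matching the observed biallelic cases.
    """
    rows = []
    idx = 0
    for lesion, extra, total, carriers, hisp, hisp_car in _SCREEN_COMPOSITION:
        hom_left = 2 if lesion == LESION_RAI else 0
        for i in range(total):
            carrier = i < carriers
            # carriers are assigned Hispanic first, then non-carrier Hispanics
            hispanic = (i < hisp_car) or (carriers <= i < carriers + (hisp - hisp_car))
            zyg = "ref"
            if carrier:
                if hispanic and hom_left > 0:
                    zyg, hom_left = "hom", hom_left - 1
                else:
                    zyg = "het"
            rows.append({
                "proband_id": f"SCR{idx:04d}",
                "lesions": ";".join((lesion,) + extra + (LESION_ALL,)),
                "carrier": carrier,
                "hispanic": hispanic,
                "zygosity": zyg,
            })
            idx += 1
    return pd.DataFrame(rows)


def reference_case_genotypes(hispanic_only: bool = True) -> list:
    """Case genotype list ('ref'/'het'/'hom') for the enrichment table."""
    df = reference_screen_cohort()
    if hispanic_only:
        df = df[df["hispanic"]]
    return list(df["zygosity"].replace({"ref": "ref"}))


# ---------------------------------------------------------------------------
# genotype cohorts and trios
# ---------------------------------------------------------------------------

@dataclass
class GenotypeSpec:
    """Parameters of a synthetic case-control genotype cohort."""

    n_cases: int = 111
    control_variant_alleles: int = 76
    control_total_alleles: int = 34592
    rho: float = 26.0  # case/control allele-frequency enrichment factor
    frac_biallelic: float = 0.0  # fraction of carriers promoted to homozygous
    n_trios: int = 12
    seed: int = 0

    def __post_init__(self):
        if self.rho < 0:
            raise ValueError("rho must be non-negative")
        if not 0.0 <= self.frac_biallelic <= 1.0:
            raise ValueError("frac_biallelic must be in [0, 1]")
        if self.case_allele_frequency > 1.0:
            raise ValueError(
                "infeasible case allele frequency rho*q = "
                f"{self.case_allele_frequency:.3g} > 1"
            )

    @property
    def control_allele_frequency(self) -> float:
        return self.control_variant_alleles / self.control_total_alleles

    @property
    def case_allele_frequency(self) -> float:
        return self.rho * self.control_allele_frequency


# trio inheritance patterns cycled through by the generator; site genotype
# maps are (proband, mother, father) at (site1, site2)
_TRIO_PATTERNS = [
    ("paternal", {"site1": ("het", "ref", "het")}),
    ("maternal", {"site1": ("het", "het", "ref")}),
    ("de_novo", {"site1": ("het", "ref", "ref")}),
    ("homozygous", {"site1": ("hom", "het", "het")}),
    ("trans", {"site1": ("het", "het", "ref"), "site2": ("het", "ref", "het")}),
    ("cis", {"site1": ("het", "het", "ref"), "site2": ("het", "het", "ref")}),
]

_SITES = {
    "site1": ("10", 72195155, "C", "T"),
    "site2": ("10", 72195210, "A", "G"),
}

_GT_FIELD = {"ref": "0/0:50,0", "het": "0/1:26,24", "hom": "1/1:1,49"}


def _trio_vcf_text(trio_genotypes: dict, samples: list) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=10,length=135534747>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    for site, (chrom, pos, ref, alt) in _SITES.items():
        gts = [
            _GT_FIELD[trio_genotypes.get(sample, {}).get(site, "ref")]
            for sample in samples
        ]
        lines.append(
            f"{chrom}\t{pos}\t{site}\t{ref}\t{alt}\t.\tPASS\t.\tGT:AD\t"
            + "\t".join(gts)
        )
    return "\n".join(lines) + "\n"


def gen_genotype_cohort(spec: GenotypeSpec):
    """Synthesise a case-control genotype cohort plus phased trios.

    Returns a dict with ``case_genotypes`` (per-case 'ref'/'het'/'hom'),
    ``vcf`` and ``ped`` text for the trio set, ``clones`` (per compound-het
    proband) and a ``truth`` record of every generated label.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.case_allele_frequency

    # two independent allele draws per case, then promote carriers to hom
    alleles = rng.random((spec.n_cases, 2)) < p
    genotypes = np.array(["ref", "het", "hom"])[alleles.sum(axis=1)]
    carriers = np.flatnonzero(genotypes != "ref")
    n_hom_target = int(round(spec.frac_biallelic * len(carriers)))
    for i in carriers[:n_hom_target]:
        genotypes[i] = "hom"

    # trios with known inheritance patterns
    trio_genotypes: dict = {}
    ped_lines = []
    truth_origin: dict = {}
    truth_biallelic: dict = {}
    clones: dict = {}
    for t in range(spec.n_trios):
        label, pattern = _TRIO_PATTERNS[t % len(_TRIO_PATTERNS)]
        pid, mid, fid = f"P{t:03d}", f"M{t:03d}", f"F{t:03d}"
        trio_genotypes[pid] = {s: g[0] for s, g in pattern.items()}
        trio_genotypes[mid] = {s: g[1] for s, g in pattern.items()}
        trio_genotypes[fid] = {s: g[2] for s, g in pattern.items()}
        ped_lines += [
            f"FAM{t:03d}\t{pid}\t{fid}\t{mid}\t1\t2",
            f"FAM{t:03d}\t{fid}\t0\t0\t1\t1",
            f"FAM{t:03d}\t{mid}\t0\t0\t2\t1",
        ]
        if label in ("paternal", "maternal", "de_novo"):
            truth_origin[(pid, "site1")] = label
            truth_biallelic[pid] = "none"
        elif label == "homozygous":
            truth_origin[(pid, "site1")] = "unknown"  # both parents carry
            truth_biallelic[pid] = "homozygous"
        elif label == "trans":
            truth_origin[(pid, "site1")] = "maternal"
            truth_origin[(pid, "site2")] = "paternal"
            truth_biallelic[pid] = "compound_het_trans"
            clones[pid] = [
                CloneObservation(f"{pid}-c{i}", "mut", "wt") for i in range(3)
            ] + [
                CloneObservation(f"{pid}-c{i + 3}", "wt", "mut") for i in range(3)
            ]
        elif label == "cis":
            truth_origin[(pid, "site1")] = "maternal"
            truth_origin[(pid, "site2")] = "maternal"
            truth_biallelic[pid] = "cis"
            clones[pid] = [
                CloneObservation(f"{pid}-c{i}", "mut", "mut") for i in range(3)
            ] + [
                CloneObservation(f"{pid}-c{i + 3}", "wt", "wt") for i in range(3)
            ]

    samples = sorted(trio_genotypes)
    return {
        "case_genotypes": list(genotypes),
        "vcf": _trio_vcf_text(trio_genotypes, samples),
        "ped": "\n".join(ped_lines) + "\n",
        "clones": clones,
        "truth": {
            "rho": spec.rho,
            "case_allele_frequency": p,
            "genotypes": {s: g for s, g in trio_genotypes.items()},
            "origin": truth_origin,
            "biallelic": truth_biallelic,
            "n_case_variant_alleles": int(
                sum({"ref": 0, "het": 1, "hom": 2}[g] for g in genotypes)
            ),
        },
    }


# ---------------------------------------------------------------------------
# read-depth cohorts
# ---------------------------------------------------------------------------

def gen_rpkm_cohort(n_samples: int, exons, deletions=(), dispersion: float = 0.1,
                    seed: int = 0, mean_depth: float = 500.0,
                    total_reads: float = 2e7):
    """Exon read-count matrix with embedded deletions.

    Counts follow a Poisson-Gamma (negative-binomial) model: the Gamma
    mixing multiplier has mean 1 and coefficient of variation
    ``dispersion``.  At ``dispersion == 0`` the counts equal their means
    exactly (noiseless limit).  ``deletions`` is a list of
    ``(sample, exon_keys, zygosity)``; deleted exon means scale by 0.5
    (het) or 0 (hom).  Returns ``(counts, totals, truth)``.
    """
    if n_samples < 8:
        raise ValueError("need at least 8 samples")
    exons = sorted(exons, key=lambda e: (e.chrom, e.start, e.end))
    keys = [e.key for e in exons]
    rng = np.random.default_rng(seed)
    samples = [f"S{i:03d}" for i in range(n_samples)]

    base = mean_depth * rng.lognormal(mean=0.0, sigma=0.3, size=len(exons))
    mu = np.tile(base[:, None], (1, n_samples))
    truth_calls = []
    for sample, exon_keys, zyg in deletions:
        if sample not in samples:
            raise ValueError(f"deletion references unknown sample {sample!r}")
        unknown = set(exon_keys) - set(keys)
        if unknown:
            raise ValueError(f"deletion references unknown exon(s): {sorted(unknown)}")
        factor = 0.5 if zyg == "het" else 0.0
        for ek in exon_keys:
            mu[keys.index(ek), samples.index(sample)] *= factor
        truth_calls.append({"sample": sample, "exons": list(exon_keys),
                            "zygosity": zyg})

    if dispersion == 0:
        counts = mu.copy()
    else:
        shape = 1.0 / dispersion ** 2
        g = rng.gamma(shape, 1.0 / shape, size=mu.shape)
        counts = rng.poisson(mu * g).astype(float)

    counts_df = pd.DataFrame(counts, index=keys, columns=samples)
    totals = pd.Series(total_reads, index=samples, dtype=float)
    return counts_df, totals, {"deletions": truth_calls}


# ---------------------------------------------------------------------------
# junction cases
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_seq(rng, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def write_fasta(sequences: dict, path):
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")
    return str(path)


def gen_junction_case(deletion_size: int = 46020, microhomology_length: int = 5,
                      insertion: str = "", repeat_families=("AluSx1", "AluSq2"),
                      strands=("+", "+"), seed: int = 0, flank: int = 150):
    """Build a deletion junction with engineered microhomology or insertion.

    The junction read is proximal flank + (shared tract | insertion) +
    distal flank; microhomology and insertion are mutually exclusive.
    Returns a dict with the reference segments, junction read, genomic
    offsets, repeat annotations and the ground-truth breakpoints.
    """
    if microhomology_length and insertion:
        raise ValueError("microhomology and insertion are mutually exclusive")
    if microhomology_length > flank // 2:
        raise ValueError("microhomology longer than the flank can carry")
    rng = np.random.default_rng(seed)
    m = microhomology_length

    for _ in range(200):  # resample until flank uniqueness constraints hold
        a = _random_seq(rng, flank)
        b = _random_seq(rng, flank)
        c = _random_seq(rng, flank)
        dseq = _random_seq(rng, flank)
        mh = _random_seq(rng, m) if m else ""
        prox_ref = a + mh + b
        dist_ref = c + mh + dseq
        read = a + mh + insertion + dseq
        first_after = (insertion or dseq)[0]
        if b[0] == first_after:  # prefix match must stop at the junction
            continue
        # in the read, the base preceding the distal-side match is the last
        # base of the retained proximal flank (or of the insertion)
        last_before = (a + insertion)[-1]
        if c[-1] == last_before:  # suffix match must stop at the junction
            continue
        if prox_ref.count(a + mh) != 1 or dist_ref.count(mh + dseq) != 1:
            continue
        break
    else:
        raise RuntimeError("could not satisfy junction uniqueness constraints")

    prox_offset = 1000
    g_p = prox_offset + flank + m  # proximal breakpoint (right edge of tract)
    g_d = g_p + deletion_size  # distal resume position
    dist_offset = g_d - flank  # so that the distal match starts at g_d

    repeats = [
        {"chrom": "10", "start": g_p - 60, "end": g_p + 60,
         "family": repeat_families[0], "strand": strands[0]},
        {"chrom": "10", "start": g_d - 60, "end": g_d + 60,
         "family": repeat_families[1], "strand": strands[1]},
    ]
    return {
        "read": read,
        "proximal_ref": prox_ref,
        "distal_ref": dist_ref,
        "proximal_offset": prox_offset,
        "distal_offset": dist_offset,
        "chrom": "10",
        "repeats": repeats,
        "truth": {
            "microhomology": mh,
            "inserted": insertion,
            "proximal_interval": (g_p - m, g_p),
            "distal_interval": (g_d, g_d + m),
            "deletion_size": deletion_size,
        },
    }
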