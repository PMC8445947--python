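"""Core domain types for cohort variant prioritization.

Internal coordinates are 1-based inclusive throughout (VCF convention);
BED-like CNV input is converted on read. Missing annotation values are
represented as ``None`` and are never silently defaulted by readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


CONSEQUENCES = frozenset({
    "nonsynonymous",
    "stopgain",
    "stoploss",
    "frameshift",
    "nonframeshift_indel",
    "splicing",
    "synonymous",
    "noncoding",
    "cnv",
})

#: consequence classes eligible for the rare-deleterious and recessive tracks
CODING_IMPACT_CONSEQUENCES = frozenset({
    "nonsynonymous", "stopgain", "stoploss", "frameshift",
    "nonframeshift_indel", "splicing",
})

#: consequence classes counted as loss-of-function for constraint look-ups
LOF_CONSEQUENCES = frozenset({"stopgain", "frameshift", "splicing"})

IMAGING_CLASSES = (
    "no_specific_pathology",
    "cerebral_infarction",
    "pvl_porencephaly",
    "ivh",
    "major_abnormality",
    "infection",
    "hie",
    "not_available",
)


class Zygosity(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    HEMI_ALT = "hemi_alt"
    MISSING = "missing"

    @property
    def carries_alt(self) -> bool:
        return self in (Zygosity.HET, Zygosity.HOM_ALT, Zygosity.HEMI_ALT)

    @property
    def alt_count(self) -> int:
        return {"hom_ref": 0, "het": 1, "hom_alt": 2,
                "hemi_alt": 1, "missing": 0}[self.value]


@dataclass
class AnnotationBundle:
    """Annotation fields consumed from the upstream annotator.

    Population frequencies are fractions in [0, 1]; ``cadd_phred`` is the
    scaled (phred-like) deleteriousness score; the five in-silico predictor
    fields use the annotator's categorical vocabularies (SIFT D/T,
    PolyPhen2-HVAR D/P/B, MutationTaster A/D/N/P, MetaSVM D/T, GERP++ RS
    real-valued). ``None`` everywhere means "not annotated".
    """

    gnomad_af: Optional[float] = None
    exac_af: Optional[float] = None
    mgrb_af: Optional[float] = None
    cadd_phred: Optional[float] = None
    sift: Optional[str] = None
    polyphen2_hvar: Optional[str] = None
    mutation_taster: Optional[str] = None
    metasvm: Optional[str] = None
    gerp_rs: Optional[float] = None
    clinvar_terms: frozenset = frozenset()
    consequence: Optional[str] = None
    gene_symbols: frozenset = frozenset()
    heteroplasmy_fraction: Optional[float] = None

    def __post_init__(self):
        for name in ("gnomad_af", "exac_af", "mgrb_af", "heteroplasmy_fraction"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v!r} outside [0, 1]")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError(f"cadd_phred={self.cadd_phred!r} negative")
        if self.consequence is not None and self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        self.clinvar_terms = frozenset(self.clinvar_terms)
        self.gene_symbols = frozenset(self.gene_symbols)

    @property
    def population_frequency(self) -> float:
        """Joint SNV/indel population frequency: max of gnomAD and ExAC.

        Missing databases are ignored; absent from both is treated as 0
        for filtering purposes.
        """
        vals = [v for v in (self.gnomad_af, self.exac_af) if v is not None]
        return max(vals) if vals else 0.0


@dataclass
class GenotypeCall:
    sample_id: str
    zygosity: Zygosity
    allele_depths: Optional[tuple[int, int]] = None

    def __post_init__(self):
        if isinstance(self.zygosity, str):
            self.zygosity = Zygosity(self.zygosity)
        if self.allele_depths is not None:
            ref_d, alt_d = self.allele_depths
            if ref_d < 0 or alt_d < 0:
                raise ValueError("allele depths must be non-negative")


@dataclass
class AnnotatedVariant:
    """One variant (one ALT allele) with its annotations and genotype calls."""

    contig: str
    position: int          # 1-based
    ref: str
    alt: str
    variant_class: str     # SNV | indel | CNV_del | CNV_dup
    span_end: Optional[int] = None  # 1-based inclusive; CNVs only
    annotations: AnnotationBundle = field(default_factory=AnnotationBundle)
    genotypes: list[GenotypeCall] = field(default_factory=list)
    pass_flag: bool = True

    def __post_init__(self):
        if self.variant_class not in ("SNV", "indel", "CNV_del", "CNV_dup"):
            raise ValueError(f"unknown variant_class {self.variant_class!r}")
        if self.span_end is None:
            self.span_end = self.position + max(len(self.ref), 1) - 1
        if self.span_end < self.position:
            raise ValueError("span_end before position")
        if self.variant_class == "SNV" and not (
                len(self.ref) == len(self.alt) == 1):
            raise ValueError("SNV requires single-base ref and alt")

    @property
    def is_cnv(self) -> bool:
        return self.variant_class.startswith("CNV")

    @property
    def key(self) -> str:
        return f"{self.contig}:{self.position}:{self.ref}:{self.alt}"

    def genotype_of(self, sample_id: str) -> Zygosity:
        for g in self.genotypes:
            if g.sample_id == sample_id:
                return g.zygosity
        return Zygosity.MISSING

    def carriers(self) -> list[str]:
        return [g.sample_id for g in self.genotypes if g.zygosity.carries_alt]


@dataclass
class PedigreeMember:
    sample_id: str
    family_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: str               # "male" | "female" | "unknown"
    affected: bool
    role: str              # proband | mother | father | sibling


class PedigreeGraph:
    """Family relationships for a cohort of proband-centred families.

    Exactly one proband per family; parent references either resolve to
    members of the same family or are ``None`` (duos/singletons).
    """

    def __init__(self, members: list[PedigreeMember]):
        self._by_id: dict[str, PedigreeMember] = {}
        self._families: dict[str, list[PedigreeMember]] = {}
        for m in members:
            if m.sample_id in self._by_id:
                raise ValueError(f"duplicate sample_id {m.sample_id!r}")
            self._by_id[m.sample_id] = m
            self._families.setdefault(m.family_id, []).append(m)
        self._check_acyclic()
        for fam, mem in self._families.items():
            probands = [m for m in mem if m.role == "proband"]
            if len(probands) != 1:
                raise ValueError(
                    f"family {fam!r} has {len(probands)} probands, expected 1")

    def _check_acyclic(self):
        for m in self._by_id.values():
            seen = set()
            stack = [m.sample_id]
            while stack:
                sid = stack.pop()
                if sid in seen:
                    raise ValueError(f"cyclic parentage involving {sid!r}")
                seen.add(sid)
                mm = self._by_id.get(sid)
                if mm is None:
                    continue
                stack.extend(p for p in (mm.father_id, mm.mother_id) if p)

    @property
    def members(self) -> list[PedigreeMember]:
        return list(self._by_id.values())

    @property
    def probands(self) -> list[PedigreeMember]:
        return [m for m in self._by_id.values() if m.role == "proband"]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    def member(self, sample_id: str) -> PedigreeMember:
        return self._by_id[sample_id]

    def family_of(self, sample_id: str) -> list[PedigreeMember]:
        return list(self._families[self._by_id[sample_id].family_id])

    def parents_of(self, sample_id: str) -> tuple[Optional[PedigreeMember],
                                                  Optional[PedigreeMember]]:
        """(father, mother) members, None where absent from the pedigree."""
        m = self._by_id[sample_id]
        father = self._by_id.get(m.father_id) if m.father_id else None
        mother = self._by_id.get(m.mother_id) if m.mother_id else None
        return father, mother

    def siblings_of(self, sample_id: str) -> list[PedigreeMember]:
        m = self._by_id[sample_id]
        return [s for s in self._families[m.family_id]
                if s.role == "sibling" and s.sample_id != sample_id]


@dataclass
class SamplePhenotype:
    sample_id: str
    sex: Optional[str] = None
    gestational_age_weeks: Optional[float] = None
    birth_weight_centile: Optional[float] = None
    autism: Optional[bool] = None
    developmental_delay: Optional[bool] = None
    epilepsy: Optional[bool] = None
    imaging_class: Optional[str] = None
    batch_id: Optional[str] = None

    def __post_init__(self):
        if (self.birth_weight_centile is not None
                and not 0 <= self.birth_weight_centile <= 100):
            raise ValueError("birth_weight_centile outside [0, 100]")
        if (self.imaging_class is not None
                and self.imaging_class not in IMAGING_CLASSES):
            raise ValueError(f"unknown imaging_class {self.imaging_class!r}")

    @property
    def comorbidity_flags(self) -> tuple:
        return (self.autism, self.developmental_delay, self.epilepsy)


AETIOLOGY_GROUPS = ("stroke_cardiovascular", "HSP", "NDD")


@dataclass
class GeneResource:
    """Per-gene reference data: panels, constraint, inheritance mode."""

    gene: str
    panels: frozenset = frozenset()
    missense_z: Optional[float] = None
    lof_oe: Optional[float] = None
    inheritance_mode: str = "unknown"   # AD | AR | XL | MT | unknown
    domino_label: Optional[str] = None
    penetrance_caveat: bool = False
    lof_mechanism: bool = False         # LoF is an established disease mechanism
    omim: bool = False
    aetiology: Optional[str] = None

    def __post_init__(self):
        self.panels = frozenset(self.panels)
        if self.inheritance_mode not in ("AD", "AR", "XL", "MT", "unknown"):
            raise ValueError(f"bad inheritance_mode {self.inheritance_mode!r}")
        if self.aetiology is not None and self.aetiology not in AETIOLOGY_GROUPS:
            raise ValueError(f"bad aetiology {self.aetiology!r}")


class GeneResourceTable:
    """Lookup wrapper over per-gene resources; unknown genes yield defaults."""

    def __init__(self, resources: list[GeneResource]):
        self._by_gene = {}
        for r in resources:
            if r.gene in self._by_gene:
                raise ValueError(f"duplicate gene {r.gene!r}")
            self._by_gene[r.gene] = r

    def get(self, gene: str) -> GeneResource:
        return self._by_gene.get(gene) or GeneResource(gene=gene)

    def __contains__(self, gene: str) -> bool:
        return gene in self._by_gene

    def genes(self) -> list[str]:
        return list(self._by_gene)

    def aetiology_of(self, genes) -> Optional[str]:
        """Aetiology group of a gene set; error if genes span two groups."""
        hits = {self._by_gene[g].aetiology for g in genes
                if g in self._by_gene and self._by_gene[g].aetiology}
        if len(hits) > 1:
            raise ValueError(f"genes {sorted(genes)} span aetiology groups {sorted(hits)}")
        return next(iter(hits)) if hits else None
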