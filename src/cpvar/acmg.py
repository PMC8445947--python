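"""ACMG-AMP five-tier classification with a penetrance-downgrade policy.

The engine auto-derives only the six tags a pipeline can compute (PVS1,
PS2, PM2, PP3, PP4, BA1/BS1); every other tag is accepted as a curated
assertion — published classifications rest on literature evidence no
pipeline can recompute, but the combining step must still be reproducible.
The published combining rules are hard-coded as an explicit rule table.

Beyond the five-tier class, findings receive a clinical-significance
category (causative / risk factor / uncertain / incidental), driven by a
curated phenotype-fit level and risk-allele flag, and an aetiology group
(stroke/cardiovascular, hereditary spastic paraplegia, or other
neurodevelopmental disorder) from gene membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .config import FilterConfig
from .types import GeneResourceTable, LOF_CONSEQUENCES

ACMG_TAGS = frozenset(
    {"PVS1"}
    | {f"PS{i}" for i in range(1, 5)}
    | {f"PM{i}" for i in range(1, 7)}
    | {f"PP{i}" for i in range(1, 6)}
    | {"BA1"}
    | {f"BS{i}" for i in range(1, 5)}
    | {f"BP{i}" for i in range(1, 8)}
)

CLASS_ORDER = {"benign": 0, "likely_benign": 1, "uncertain": 2,
               "likely_pathogenic": 3, "pathogenic": 4}


class ContradictoryEvidenceError(ValueError):
    pass


@dataclass
class ACMGEvidence:
    tags: set = field(default_factory=set)
    provenance: dict = field(default_factory=dict)   # tag -> "auto"|"curated"

    def add(self, tag: str, provenance: str) -> None:
        if tag not in ACMG_TAGS:
            raise ValueError(f"unknown ACMG tag {tag!r}")
        self.tags.add(tag)
        self.provenance[tag] = provenance


@dataclass
class ClassifiedFinding:
    variant_keys: tuple
    case_id: str
    genes: tuple
    acmg_class: str
    clinical_significance: str = "uncertain"
    aetiology: Optional[str] = None
    downgrade_applied: bool = False
    evidence: Optional[ACMGEvidence] = None
    is_cnv: bool = False
    trace: list = field(default_factory=list)
    variants: tuple = ()      # underlying AnnotatedVariant objects, if any


def derive_acmg_evidence(variant, verdict, inheritance, gene_resource,
                         phenotype_fit: str = "unknown",
                         curated_tags=(), config: Optional[FilterConfig] = None
                         ) -> ACMGEvidence:
    """Auto-derive computable tags and merge curated assertions.

    Auto tags: PVS1 (loss-of-function class in a LoF-intolerant gene with
    an established LoF disease mechanism), PM2 (below the rare-variant
    frequency threshold), PP3 (>= 3 deleterious in-silico votes), PS2
    (trio-confirmed de novo), PP4 (curated phenotype fit), BA1/BS1
    (above the benign frequency thresholds). PM2 together with BA1 is a
    contradiction and raises.
    """
    config = config or FilterConfig()
    ev = ACMGEvidence()
    a = variant.annotations
    lof = (a.consequence in LOF_CONSEQUENCES
           or variant.variant_class == "CNV_del")
    if lof and any(
            gene_resource.get(g).lof_mechanism
            and gene_resource.get(g).lof_oe is not None
            and gene_resource.get(g).lof_oe < config.intolerant_lof_oe
            for g in a.gene_symbols):
        ev.add("PVS1", "auto")
    freq = a.population_frequency
    if freq < config.filter1_af:
        ev.add("PM2", "auto")
    if freq > config.ba1_af:
        ev.add("BA1", "auto")
    elif freq > config.bs1_af:
        ev.add("BS1", "auto")
    if verdict is not None and verdict.insilico_votes >= config.votes_min:
        ev.add("PP3", "auto")
    if inheritance is not None and inheritance.value == "de_novo":
        ev.add("PS2", "auto")
    if phenotype_fit == "full":
        ev.add("PP4", "auto")
    for tag in curated_tags:
        ev.add(tag, "curated")
    if "PM2" in ev.tags and "BA1" in ev.tags:
        raise ContradictoryEvidenceError(
            f"PM2 and BA1 both asserted for {variant.key}")
    return ev


def _counts(tags) -> dict:
    return {
        "pvs": int("PVS1" in tags),
        "ps": sum(1 for t in tags if t.startswith("PS")),
        "pm": sum(1 for t in tags if t.startswith("PM")),
        "pp": sum(1 for t in tags if t.startswith("PP")),
        "ba": int("BA1" in tags),
        "bs": sum(1 for t in tags if t.startswith("BS")),
        "bp": sum(1 for t in tags if t.startswith("BP")),
    }


def combine_acmg(evidence) -> str:
    """Combine ACMG tags into a five-tier class by the published rules.

    Accepts an :class:`ACMGEvidence` or a bare tag collection. Pathogenic
    and benign branches are evaluated independently; meeting criteria on
    both sides is a conflict and yields ``uncertain``.
    """
    tags = evidence.tags if isinstance(evidence, ACMGEvidence) else set(evidence)
    c = _counts(tags)
    pvs, ps, pm, pp = c["pvs"], c["ps"], c["pm"], c["pp"]
    ba, bs, bp = c["ba"], c["bs"], c["bp"]

    if pvs and (ps >= 1 or pm >= 2 or (pm == 1 and pp >= 1) or pp >= 2):
        path = "pathogenic"
    elif ps >= 2:
        path = "pathogenic"
    elif ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2)
                      or (pm == 1 and pp >= 4)):
        path = "pathogenic"
    elif pvs and pm == 1:
        path = "likely_pathogenic"
    elif ps == 1 and 1 <= pm <= 2:
        path = "likely_pathogenic"
    elif ps == 1 and pp >= 2:
        path = "likely_pathogenic"
    elif pm >= 3:
        path = "likely_pathogenic"
    elif pm == 2 and pp >= 2:
        path = "likely_pathogenic"
    elif pm == 1 and pp >= 4:
        path = "likely_pathogenic"
    else:
        path = None

    if ba or bs >= 2:
        ben = "benign"
    elif (bs == 1 and bp == 1) or bp >= 2:
        ben = "likely_benign"
    else:
        ben = None

    if path and ben:
        return "uncertain"
    return path or ben or "uncertain"


def apply_penetrance_downgrade(finding: ClassifiedFinding,
                               inheritance, parent_affected: bool,
                               gene_resource: GeneResourceTable
                               ) -> ClassifiedFinding:
    """Downgrade inherited P/LP findings lacking a penetrance caveat.

    A P/LP variant demonstrably inherited from an unaffected parent is
    reclassified as uncertain unless incomplete penetrance or variable
    expressivity is documented for the gene. The rule never applies to
    recessive- or mitochondrial-mode genes (unaffected carrier parents
    are expected there) and never upgrades.
    """
    if finding.acmg_class not in ("pathogenic", "likely_pathogenic"):
        return finding
    label = inheritance.value if hasattr(inheritance, "value") else inheritance
    if label not in ("maternal", "paternal"):
        return finding
    if parent_affected:
        return finding
    modes = {gene_resource.get(g).inheritance_mode for g in finding.genes}
    if modes & {"AR", "MT"}:
        return finding
    if any(gene_resource.get(g).penetrance_caveat for g in finding.genes):
        finding.trace.append(
            "inherited from unaffected parent; penetrance caveat "
            "documented, class retained")
        return finding
    finding.trace.append(
        f"penetrance downgrade: {finding.acmg_class} -> uncertain "
        "(inherited from unaffected parent, no penetrance caveat)")
    finding.acmg_class = "uncertain"
    finding.downgrade_applied = True
    return finding


def assign_clinical_significance(finding: ClassifiedFinding,
                                 phenotype_fit: str,
                                 risk_allele_flag: bool) -> ClassifiedFinding:
    """Map (class, phenotype fit, risk-allele flag) to a clinical category.

    causative: P/LP fully fitting the presentation; risk factor: P/LP
    conferring aetiology-consistent predisposition (partial fit) or a
    curated risk allele of any class; incidental: P/LP unrelated to the
    presentation; otherwise uncertain.
    """
    plp = finding.acmg_class in ("pathogenic", "likely_pathogenic")
    if risk_allele_flag:
        sig = "risk_factor"
    elif plp and phenotype_fit == "full":
        sig = "causative"
    elif plp and phenotype_fit == "partial":
        sig = "risk_factor"
    elif plp and phenotype_fit == "none":
        sig = "incidental"
    else:
        sig = "uncertain"
    finding.clinical_significance = sig
    finding.trace.append(
        f"clinical significance {sig} (class={finding.acmg_class}, "
        f"fit={phenotype_fit}, risk_allele={risk_allele_flag})")
    return finding


def assign_aetiology(finding: ClassifiedFinding,
                     gene_resource: GeneResourceTable) -> ClassifiedFinding:
    """Assign the aetiology group from gene membership; groups are disjoint."""
    finding.aetiology = gene_resource.aetiology_of(finding.genes)
    if finding.aetiology:
        finding.trace.append(f"aetiology {finding.aetiology}")
    return finding
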