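"""Inheritance labelling and compound-heterozygote phase resolution.

Labels are assigned from the proband's genotype and whatever parental
genotypes the pedigree provides: full trios support de novo calls, duos
support single-parent ("maternal" / "not maternal") calls, singletons are
always unknown. A parent with a no-call genotype at the site is treated
the same as an absent parent, with a note recording the distinction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

from .types import AnnotatedVariant, PedigreeGraph, Zygosity

MT_CONTIGS = frozenset({"MT", "chrM", "chrMT", "M", "NC_012920.1"})
X_CONTIGS = frozenset({"X", "chrX"})


@dataclass
class InheritanceLabel:
    value: str                       # de_novo | maternal | paternal |
    #                                  biparental | not_maternal |
    #                                  not_paternal | unknown
    confidence_note: str = ""

    def __eq__(self, other):
        if isinstance(other, str):
            return self.value == other
        return (self.value, self.confidence_note) == \
               (other.value, other.confidence_note)


@dataclass
class PhasePair:
    variant_a: AnnotatedVariant
    variant_b: AnnotatedVariant
    phase: str                       # trans | cis | unknown
    evidence: str                    # parental_genotypes | long_read | none

    @property
    def key(self) -> frozenset:
        return frozenset((self.variant_a.key, self.variant_b.key))


def _parent_genotype(variant, member) -> Optional[Zygosity]:
    """Parent's genotype, or None if the parent is absent or a no-call."""
    if member is None:
        return None
    g = variant.genotype_of(member.sample_id)
    return None if g == Zygosity.MISSING else g


def assign_inheritance(variant: AnnotatedVariant,
                       pedigree: PedigreeGraph,
                       proband_id: str) -> InheritanceLabel:
    """Label one proband variant from the available parental genotypes.

    Pure function of genotypes and pedigree structure. Mendelian
    impossibilities (e.g. an autosomal homozygote with both parents
    reference) are flagged, never silently relabelled. Sibling genotypes
    only refine the confidence note.
    """
    pg = variant.genotype_of(proband_id)
    if not pg.carries_alt:
        raise ValueError(
            f"proband {proband_id} does not carry {variant.key}")
    father, mother = pedigree.parents_of(proband_id)

    if variant.contig in MT_CONTIGS:
        return _mitochondrial_label(variant, mother)

    gm = _parent_genotype(variant, mother)
    gf = _parent_genotype(variant, father)
    nocall_notes = []
    if mother is not None and gm is None:
        nocall_notes.append("maternal genotype no-call, treated as absent")
    if father is not None and gf is None:
        nocall_notes.append("paternal genotype no-call, treated as absent")

    label = _label_from_parents(variant, pg, gm, gf)
    notes = [label.confidence_note] if label.confidence_note else []
    notes.extend(nocall_notes)
    notes.extend(_sibling_notes(variant, pedigree, proband_id))
    label.confidence_note = "; ".join(notes)
    return label


def _mitochondrial_label(variant, mother) -> InheritanceLabel:
    # maternal when detected in the mother at any heteroplasmy
    gm = _parent_genotype(variant, mother)
    if gm is not None and gm.carries_alt:
        return InheritanceLabel("maternal",
                                "detected in maternal sample")
    return InheritanceLabel("unknown")


def _label_from_parents(variant, pg: Zygosity,
                        gm: Optional[Zygosity],
                        gf: Optional[Zygosity]) -> InheritanceLabel:
    hemi_x = (pg == Zygosity.HEMI_ALT and variant.contig in X_CONTIGS)

    if gm is None and gf is None:
        return InheritanceLabel("unknown")

    if hemi_x:
        # male X: only the maternal genotype is informative
        if gm is None:
            return InheritanceLabel("unknown")
        if gm.carries_alt:
            return InheritanceLabel("maternal")
        if gf is not None:
            return InheritanceLabel("de_novo")
        return InheritanceLabel("not_maternal")

    if pg == Zygosity.HOM_ALT:
        if gm is not None and gf is not None:
            if gm.carries_alt and gf.carries_alt:
                return InheritanceLabel("biparental")
            return InheritanceLabel("unknown", "mendelian_conflict")
        present = gm if gm is not None else gf
        if not present.carries_alt:
            return InheritanceLabel("unknown", "mendelian_conflict")
        return InheritanceLabel("unknown",
                                "one parent carrier, other parent absent")

    # heterozygous proband
    if gm is not None and gf is not None:
        m_alt, f_alt = gm.carries_alt, gf.carries_alt
        if not m_alt and not f_alt:
            return InheritanceLabel("de_novo")
        if m_alt and not f_alt:
            return InheritanceLabel("maternal")
        if f_alt and not m_alt:
            return InheritanceLabel("paternal")
        return InheritanceLabel("unknown", "both parents carry the allele")
    if gm is not None:
        return InheritanceLabel("maternal") if gm.carries_alt \
            else InheritanceLabel("not_maternal")
    return InheritanceLabel("paternal") if gf.carries_alt \
        else InheritanceLabel("not_paternal")


def _sibling_notes(variant, pedigree, proband_id) -> list[str]:
    notes = []
    for sib in pedigree.siblings_of(proband_id):
        g = variant.genotype_of(sib.sample_id)
        if g == Zygosity.MISSING:
            continue
        if g.carries_alt:
            notes.append(f"shared by sibling {sib.sample_id}")
        else:
            notes.append(f"not shared by sibling {sib.sample_id}")
    return notes


# --------------------------------------------------------- compound hets

_FROM_MOTHER = {"maternal", "not_paternal"}
_FROM_FATHER = {"paternal", "not_maternal"}


def _origin(label: InheritanceLabel) -> Optional[str]:
    if label.value in _FROM_MOTHER:
        return "mother"
    if label.value in _FROM_FATHER:
        return "father"
    return None


def _phase_from_labels(la: InheritanceLabel,
                       lb: InheritanceLabel) -> Optional[str]:
    oa, ob = _origin(la), _origin(lb)
    if oa is None or ob is None:
        return None
    return "trans" if oa != ob else "cis"


def detect_compound_het(variants_in_gene: list[AnnotatedVariant],
                        pedigree: PedigreeGraph,
                        proband_id: str,
                        external_phase: Optional[dict] = None
                        ) -> list[PhasePair]:
    """Pair heterozygous proband variants sharing a gene and phase them.

    Phase comes from parental genotypes where they resolve the parental
    origin of both variants; an external long-read phasing result (map of
    ``frozenset({key_a, key_b}) -> phase``) overrides genotype-derived
    phase. Pairs in trans are recessive candidates, cis pairs are reported
    but rejected from candidacy, unknown pairs stay "possible".
    """
    external_phase = external_phase or {}
    hets = [v for v in variants_in_gene
            if v.genotype_of(proband_id) == Zygosity.HET]
    pairs: list[PhasePair] = []
    for va, vb in combinations(hets, 2):
        shared = va.annotations.gene_symbols & vb.annotations.gene_symbols
        if not shared:
            continue
        key = frozenset((va.key, vb.key))
        if key in external_phase:
            pairs.append(PhasePair(va, vb, external_phase[key], "long_read"))
            continue
        la = assign_inheritance(va, pedigree, proband_id)
        lb = assign_inheritance(vb, pedigree, proband_id)
        phase = _phase_from_labels(la, lb)
        if phase is None:
            pairs.append(PhasePair(va, vb, "unknown", "none"))
        else:
            pairs.append(PhasePair(va, vb, phase, "parental_genotypes"))
    return pairs
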