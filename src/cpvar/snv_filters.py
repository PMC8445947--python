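"""SNV/indel prioritization: batch exclusion and the three filter tracks.

Track 1 (rare deleterious): coding-impact consequence, population
frequency < 1e-4, CADD scaled score > 20 where available, supported by
either >= 3 of 5 deleterious in-silico predictor votes or membership of a
disease gene panel.

Track 2 (recessive): frequency < 1e-2 and homozygous/hemizygous, part of
a trans-or-unresolved compound-het pair, or a configured di-genic pair.

Track 3 (known pathogenic): any variant, coding or not, carrying a
ClinVar "pathogenic" / "likely pathogenic" assertion, plus a second-hit
search in recessive genes.

A fourth track flags rare high-impact variants in variation-intolerant
genes (missense Z > 2 or LoF o/e < 0.5) as candidate VUS in individuals
left undiagnosed by the other tracks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

from .config import FilterConfig
from .inheritance import PhasePair, detect_compound_het
from .types import (
    AnnotatedVariant,
    AnnotationBundle,
    GeneResourceTable,
    PedigreeGraph,
    Zygosity,
    CODING_IMPACT_CONSEQUENCES,
    LOF_CONSEQUENCES,
)


@dataclass
class FilterVerdict:
    """Per-(proband, variant) record of which tracks passed and why."""

    variant: AnnotatedVariant
    proband_id: str
    tracks_passed: set = field(default_factory=set)
    insilico_votes: int = 0
    insilico_available: int = 0
    panels_hit: set = field(default_factory=set)
    clinvar_match: set = field(default_factory=set)
    recessive_partner: Optional[PhasePair] = None
    notes: list = field(default_factory=list)


class BatchConfigurationError(RuntimeError):
    pass


def batch_allele_filter(variants: list[AnnotatedVariant],
                        batch_map: dict[str, str],
                        config: Optional[FilterConfig] = None
                        ) -> list[AnnotatedVariant]:
    """Drop variants whose ALT allele count exceeds 2 within any batch.

    ``batch_map`` assigns every sequenced sample to its joint-calling
    batch; a carrier without a batch assignment is a configuration error.
    Batches smaller than the minimum joint-calling size trigger a warning.
    """
    config = config or FilterConfig()
    batch_sizes: dict[str, int] = {}
    for b in batch_map.values():
        batch_sizes[b] = batch_sizes.get(b, 0) + 1
    for b, n in sorted(batch_sizes.items()):
        if n < config.min_batch_size:
            warnings.warn(
                f"batch {b!r} has {n} samples "
                f"(< {config.min_batch_size})", stacklevel=2)
    surviving = []
    for v in variants:
        counts: dict[str, int] = {}
        for g in v.genotypes:
            if not g.zygosity.carries_alt:
                continue
            batch = batch_map.get(g.sample_id)
            if batch is None:
                raise BatchConfigurationError(
                    f"carrier {g.sample_id!r} of {v.key} has no batch_id")
            counts[batch] = counts.get(batch, 0) + g.zygosity.alt_count
        if not counts or max(counts.values()) <= config.batch_ac_max:
            surviving.append(v)
    return surviving


def insilico_vote(annotations: AnnotationBundle,
                  config: Optional[FilterConfig] = None) -> tuple[int, int]:
    """Count deleterious calls among the five in-silico predictors.

    Criteria: SIFT = D; PolyPhen2-HVAR in {D, P}; MutationTaster in
    {A, D}; MetaSVM = D; GERP++ RS > 4. Returns (votes, available) where
    ``available`` counts non-missing predictors.
    """
    config = config or FilterConfig()
    a = annotations
    checks = [
        (a.sift, lambda v: v == "D"),
        (a.polyphen2_hvar, lambda v: v in ("D", "P")),
        (a.mutation_taster, lambda v: v in ("A", "D")),
        (a.metasvm, lambda v: v == "D"),
        (a.gerp_rs, lambda v: v > config.gerp_min),
    ]
    available = sum(1 for val, _ in checks if val is not None)
    votes = sum(1 for val, ok in checks if val is not None and ok(val))
    return votes, available


def filter1_rare_deleterious(variant: AnnotatedVariant,
                             gene_resource: GeneResourceTable,
                             config: FilterConfig,
                             verdict: FilterVerdict) -> bool:
    """Rare-deleterious track predicate; records evidence on the verdict."""
    a = variant.annotations
    votes, available = insilico_vote(a, config)
    verdict.insilico_votes = votes
    verdict.insilico_available = available
    panels = set()
    for gene in a.gene_symbols:
        panels |= gene_resource.get(gene).panels
    verdict.panels_hit = panels

    if a.consequence not in CODING_IMPACT_CONSEQUENCES:
        return False
    if a.population_frequency >= config.filter1_af:
        return False
    if a.cadd_phred is not None and a.cadd_phred <= config.cadd_min:
        return False
    vote_ok = votes >= config.votes_min
    panel_ok = bool(panels)
    if config.evidence_mode == "all":
        return vote_ok and panel_ok
    return vote_ok or panel_ok


def filter2_recessive(variants_by_gene: dict[str, list[AnnotatedVariant]],
                      pedigree: PedigreeGraph,
                      proband_id: str,
                      config: FilterConfig,
                      verdicts: dict[str, FilterVerdict],
                      external_phase: Optional[dict] = None) -> None:
    """Recessive track over one proband's variants grouped by gene.

    Candidates: frequency < 1e-2 and (homozygous/hemizygous, or member of
    a trans/unresolved compound-het pair, or paired across a configured
    di-genic gene-pair list). Cis pairs are recorded but not candidates.
    """
    digenic = {frozenset(p) for p in config.digenic_pairs}

    def freq_ok(v):
        return (v.annotations.population_frequency < config.filter2_af
                and v.annotations.consequence in CODING_IMPACT_CONSEQUENCES)

    rare_by_gene = {g: [v for v in vs if freq_ok(v)]
                    for g, vs in variants_by_gene.items()}
    for gene, vs in rare_by_gene.items():
        for v in vs:
            z = v.genotype_of(proband_id)
            if z in (Zygosity.HOM_ALT, Zygosity.HEMI_ALT):
                verdicts[v.key].tracks_passed.add("filter2")
                verdicts[v.key].notes.append(f"homozygous in {gene}")
        pairs = detect_compound_het(vs, pedigree, proband_id, external_phase)
        for pair in pairs:
            for v in (pair.variant_a, pair.variant_b):
                if pair.phase in ("trans", "unknown"):
                    verdicts[v.key].tracks_passed.add("filter2")
                    verdicts[v.key].recessive_partner = pair
                else:
                    verdicts[v.key].notes.append(
                        "compound-het partner in cis; rejected")
                    verdicts[v.key].recessive_partner = pair
    # di-genic pairs across genes (off unless a pair list is configured)
    if digenic:
        for pair in digenic:
            genes = sorted(pair)
            if len(genes) != 2:
                raise ValueError("di-genic entries must be gene pairs")
            ga, gb = genes
            for va in rare_by_gene.get(ga, []):
                for vb in rare_by_gene.get(gb, []):
                    if (va.genotype_of(proband_id).carries_alt
                            and vb.genotype_of(proband_id).carries_alt):
                        for v in (va, vb):
                            verdicts[v.key].tracks_passed.add("filter2")
                            verdicts[v.key].notes.append(
                                f"di-genic pair {ga}/{gb}")


_PATHOGENIC_TOKENS = ("pathogenic", "likely pathogenic")


def clinvar_is_pathogenic(terms) -> set:
    """ClinVar terms matching the P/LP significance vocabulary.

    Matching is against whole significance categories, case-insensitively,
    tolerating ClinVar's slash/comma-joined composites ("Pathogenic/Likely
    pathogenic"). Benign and conflicting-interpretation strings never match.
    """
    matched = set()
    for term in terms:
        if "conflicting" in term.lower():
            continue
        for category in term.replace(",", "/").split("/"):
            if category.strip().lower() in _PATHOGENIC_TOKENS:
                matched.add(term)
    return matched


def filter3_known_pathogenic(variant: AnnotatedVariant,
                             verdict: FilterVerdict) -> bool:
    """Known-pathogenic track: any ClinVar P/LP assertion (non-coding
    variants included)."""
    matched = clinvar_is_pathogenic(variant.annotations.clinvar_terms)
    verdict.clinvar_match = matched
    return bool(matched)


def second_hit_search(proband_id: str, gene: str,
                      all_variants: list[AnnotatedVariant],
                      cnv_calls: list[AnnotatedVariant],
                      gene_resource: GeneResourceTable,
                      exclude_keys: Optional[set] = None
                      ) -> list[AnnotatedVariant]:
    """Look for a second hit in a recessive gene carrying one P/LP variant.

    Returns every other variant the proband carries in the gene — coding
    or not, regardless of the other tracks' thresholds — plus any CNV
    overlapping the gene, ranked by population frequency then descending
    CADD. Genes without a recessive inheritance mode return nothing.
    """
    if gene_resource.get(gene).inheritance_mode != "AR":
        return []
    exclude_keys = exclude_keys or set()
    hits = []
    for v in all_variants:
        if v.key in exclude_keys:
            continue
        if gene in v.annotations.gene_symbols and \
                v.genotype_of(proband_id).carries_alt:
            hits.append(v)
    for c in cnv_calls:
        if c.key in exclude_keys:
            continue
        if gene in c.annotations.gene_symbols and \
                c.genotype_of(proband_id).carries_alt:
            hits.append(c)
    def rank(v):
        a = v.annotations
        freq = a.mgrb_af if v.is_cnv else a.population_frequency
        cadd = a.cadd_phred if a.cadd_phred is not None else -1.0
        return (freq if freq is not None else 0.0, -cadd, v.key)
    return sorted(hits, key=rank)


def intolerant_gene_vus(variant: AnnotatedVariant,
                        gene_resource: GeneResourceTable,
                        individual_diagnosed: bool,
                        config: FilterConfig) -> bool:
    """Rare high-impact VUS in a variation-intolerant gene.

    Only in individuals with no causative/risk P/LP finding; requires
    frequency < 1e-4, CADD > 20, and constraint evidence matched to the
    variant class: missense in a gene with missense Z > 2, or a
    loss-of-function variant in a gene with LoF o/e < 0.5.
    """
    if individual_diagnosed:
        return False
    a = variant.annotations
    if a.population_frequency >= config.filter1_af:
        return False
    if a.cadd_phred is None or a.cadd_phred <= config.cadd_min:
        return False
    for gene in a.gene_symbols:
        r = gene_resource.get(gene)
        if (a.consequence == "nonsynonymous" and r.missense_z is not None
                and r.missense_z > config.intolerant_missense_z):
            return True
        if (a.consequence in LOF_CONSEQUENCES and r.lof_oe is not None
                and r.lof_oe < config.intolerant_lof_oe):
            return True
    return False


def prioritize_proband(proband_id: str,
                       variants: list[AnnotatedVariant],
                       pedigree: PedigreeGraph,
                       gene_resource: GeneResourceTable,
                       config: Optional[FilterConfig] = None,
                       cnv_calls: Optional[list[AnnotatedVariant]] = None,
                       external_phase: Optional[dict] = None
                       ) -> dict[str, FilterVerdict]:
    """Run tracks 1-3 over one proband's batch-surviving variants.

    Returns verdicts keyed by variant key; the prioritized set is the
    union of the track pass-sets. The intolerant-VUS track runs later,
    once diagnosed status is known (see :func:`intolerant_gene_vus`).
    """
    config = config or FilterConfig()
    cnv_calls = cnv_calls or []
    mine = [v for v in variants if v.genotype_of(proband_id).carries_alt]
    verdicts = {v.key: FilterVerdict(v, proband_id) for v in mine}

    by_gene: dict[str, list[AnnotatedVariant]] = {}
    for v in mine:
        for g in v.annotations.gene_symbols:
            by_gene.setdefault(g, []).append(v)

    for v in mine:
        if filter1_rare_deleterious(v, gene_resource, config, verdicts[v.key]):
            verdicts[v.key].tracks_passed.add("filter1")
    filter2_recessive(by_gene, pedigree, proband_id, config, verdicts,
                      external_phase)
    for v in mine:
        if filter3_known_pathogenic(v, verdicts[v.key]):
            verdicts[v.key].tracks_passed.add("filter3")
            # second-hit search in recessive genes
            for gene in v.annotations.gene_symbols:
                for hit in second_hit_search(
                        proband_id, gene, mine, cnv_calls, gene_resource,
                        exclude_keys={v.key}):
                    if not hit.is_cnv:
                        verdicts[hit.key].tracks_passed.add("filter3")
                        verdicts[hit.key].notes.append(
                            f"second hit in {gene}")
    return verdicts
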