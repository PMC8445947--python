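"""CNV prioritization: rarity, detection pass, gene impact, panel/OMIM overlap.

Intervals use the internal 1-based inclusive convention; a CNV touching a
gene's single terminal base overlaps it. "Impacting coding region" is
evaluated against a supplied gene-model table (gene, contig, coding start,
coding end) with any >= 1 bp overlap counting — upstream callers do not
report a reciprocal-overlap fraction. Orthogonal wet-lab validation is a
human step; prioritized calls carry a ``needs_validation`` flag instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .config import FilterConfig
from .types import AnnotatedVariant, GeneResourceTable


@dataclass
class CnvEvidence:
    cnv: AnnotatedVariant
    criteria: set = field(default_factory=set)  # subset of {coding, OMIM, panel}
    needs_validation: bool = True

    @property
    def prioritized(self) -> bool:
        return bool(self.criteria)


def cnv_rare_filter(cnvs: list[AnnotatedVariant],
                    config: Optional[FilterConfig] = None
                    ) -> list[AnnotatedVariant]:
    """Keep gene-affecting calls passing detection with MGRB AF < 1%."""
    config = config or FilterConfig()
    out = []
    for c in cnvs:
        af = c.annotations.mgrb_af
        if not c.pass_flag:
            continue
        if af is not None and af >= config.cnv_af_max:
            continue
        if not c.annotations.gene_symbols:
            continue
        out.append(c)
    return out


def _overlaps(cnv: AnnotatedVariant, contig: str, start: int, end: int) -> bool:
    # 1-based inclusive on both sides
    return cnv.contig == contig and cnv.position <= end and \
        cnv.span_end >= start


def cnv_prioritize(cnvs: list[AnnotatedVariant],
                   gene_resource: GeneResourceTable,
                   gene_model: Optional[list[dict]] = None
                   ) -> list[CnvEvidence]:
    """Attach prioritization evidence to rare-filtered CNV calls.

    Criteria: overlap of a coding region in the gene model, overlap of an
    OMIM disease gene, overlap of a panel gene. A call is prioritized when
    at least one criterion hits.
    """
    gene_model = gene_model or []
    out = []
    for c in cnvs:
        ev = CnvEvidence(c)
        for g in c.annotations.gene_symbols:
            r = gene_resource.get(g)
            if r.omim:
                ev.criteria.add("OMIM")
            if r.panels:
                ev.criteria.add("panel")
        for gm in gene_model:
            if gm["gene"] in c.annotations.gene_symbols and _overlaps(
                    c, gm["contig"], gm["coding_start"], gm["coding_end"]):
                ev.criteria.add("coding")
        out.append(ev)
    return out
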