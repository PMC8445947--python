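"""Filter and classification thresholds with study defaults."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

#: default INFO-key mapping for annotated VCF input (annotator dialects vary)
DEFAULT_INFO_KEYS = {
    "gnomad_af": "GNOMAD_AF",
    "exac_af": "EXAC_AF",
    "cadd_phred": "CADD_PHRED",
    "sift": "SIFT",
    "polyphen2_hvar": "PP2_HVAR",
    "mutation_taster": "MT",
    "metasvm": "METASVM",
    "gerp_rs": "GERP_RS",
    "clinvar_terms": "CLNSIG",
    "gene_symbols": "GENE",
    "consequence": "CSQ_CLASS",
    "heteroplasmy_fraction": "HET_FRAC",
}


@dataclass
class FilterConfig:
    """Thresholds of the three SNV tracks, the CNV track and the VUS track.

    Defaults are the published study settings: rare-deleterious frequency
    < 1e-4, recessive frequency < 1e-2, CADD scaled score > 20, GERP++ RS
    > 4, >= 3 of 5 deleterious in-silico votes, batch allele count <= 2,
    CNV population frequency < 1%, missense Z > 2 and LoF o/e < 0.5 for
    variation-intolerant genes.
    """

    filter1_af: float = 1.0e-4
    filter2_af: float = 1.0e-2
    cadd_min: float = 20.0
    gerp_min: float = 4.0
    votes_min: int = 3
    batch_ac_max: int = 2
    min_batch_size: int = 40
    cnv_af_max: float = 0.01
    intolerant_missense_z: float = 2.0
    intolerant_lof_oe: float = 0.5
    # ACMG benign frequency thresholds (BA1 stand-alone, BS1 strong)
    ba1_af: float = 0.05
    bs1_af: float = 0.01
    # how Filter 1 combines the in-silico vote with panel membership
    evidence_mode: str = "any"            # "any" (OR, default) | "all" (AND)
    chisq_continuity_correction: bool = False
    digenic_pairs: tuple = ()             # optional ((geneA, geneB), ...)
    mlpa_thresholds: tuple = (0.25, 0.75, 1.25)

    def __post_init__(self):
        if self.evidence_mode not in ("any", "all"):
            raise ValueError("evidence_mode must be 'any' or 'all'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["digenic_pairs"] = [list(p) for p in self.digenic_pairs]
        d["mlpa_thresholds"] = list(self.mlpa_thresholds)
        return d

    @classmethod
    def from_yaml(cls, path) -> "FilterConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "digenic_pairs" in raw:
            raw["digenic_pairs"] = tuple(tuple(p) for p in raw["digenic_pairs"])
        if "mlpa_thresholds" in raw:
            raw["mlpa_thresholds"] = tuple(raw["mlpa_thresholds"])
        return cls(**raw)
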