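"""End-to-end orchestration: ingest -> filters -> classification -> stats.

Stages run in a fixed order (ingest, batch filter, inheritance, SNV
tracks, CNV tracks, classification, significance/aetiology, statistics);
per-stage record counts are logged and a failure in one individual flags
that individual without aborting the cohort run. Reports are byte-stable
for identical inputs and configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .acmg import (
    apply_penetrance_downgrade,
    assign_aetiology,
    assign_clinical_significance,
    combine_acmg,
    derive_acmg_evidence,
    ClassifiedFinding,
)
from .config import FilterConfig
from .inheritance import assign_inheritance
from .io import (
    CuratedEvidence,
    read_annotated_vcf,
    read_cnv_table,
    read_curated_evidence,
    read_external_phase,
    read_gene_model,
    read_pedigree,
    read_phenotype_table,
    read_gene_resource_table,
)
from .cnv_filters import cnv_prioritize, cnv_rare_filter
from .snv_filters import batch_allele_filter, intolerant_gene_vus, \
    prioritize_proband
from .stats import yield_summary, pct, YieldSummary

log = logging.getLogger("cpvar")

LOF_CLASSES = frozenset({"stopgain", "frameshift", "splicing"})


@dataclass
class RunManifest:
    config: dict
    input_digests: dict
    version: str
    stage_counts: dict = field(default_factory=dict)

    @property
    def digest(self) -> str:
        payload = json.dumps(
            {"config": self.config, "inputs": self.input_digests,
             "version": self.version}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    findings: list
    verdicts: dict                  # proband -> {variant_key -> FilterVerdict}
    diagnosed_ids: set
    vus_intolerant_ids: set
    summary: Optional[YieldSummary]
    manifest: RunManifest
    flagged_individuals: dict = field(default_factory=dict)


class MissingInputError(FileNotFoundError):
    pass


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _mechanism_of(finding: ClassifiedFinding, gene_resource) -> str:
    if finding.is_cnv:
        return "cnv"
    modes = {gene_resource.get(g).inheritance_mode for g in finding.genes}
    consequences = {v.annotations.consequence for v in finding.variants}
    if "AD" in modes:
        return "ad_lof" if consequences & LOF_CLASSES else "ad_missense"
    if "AR" in modes:
        return "ar"
    if "MT" in modes:
        return "mt"
    if "XL" in modes:
        return "xl"
    return "other"


def classify_variant(variant, verdict, label, gene_resource, evidence_store,
                     case_id, parent_affected: bool,
                     config: FilterConfig) -> ClassifiedFinding:
    """Classify one prioritized variant for one proband."""
    key = variant.key
    fit = evidence_store.fit_for(key)
    risk = key in evidence_store.risk_alleles
    ev = derive_acmg_evidence(
        variant, verdict, label, gene_resource, phenotype_fit=fit,
        curated_tags=evidence_store.tags_for(key), config=config)
    finding = ClassifiedFinding(
        variant_keys=(key,), case_id=case_id,
        genes=tuple(sorted(variant.annotations.gene_symbols)),
        acmg_class=combine_acmg(ev), evidence=ev,
        is_cnv=variant.is_cnv)
    finding.variants = (variant,)
    finding.trace.append(
        f"combined {len(ev.tags)} tags -> {finding.acmg_class}")
    finding = apply_penetrance_downgrade(finding, label, parent_affected,
                                         gene_resource)
    finding = assign_clinical_significance(finding, fit, risk)
    finding = assign_aetiology(finding, gene_resource)
    return finding


def run_pipeline(inputs: dict, config: Optional[FilterConfig] = None
                 ) -> PipelineResult:
    """Run the full cohort pipeline from input file paths.

    ``inputs`` keys: vcf, ped, cnv, phenotypes, gene_resources; optional:
    curated_evidence, external_phase, gene_model. All required inputs are
    checked up front and missing ones reported together.
    """
    config = config or FilterConfig()
    required = ("vcf", "ped", "cnv", "phenotypes", "gene_resources")
    missing = [k for k in required
               if k not in inputs or not Path(inputs[k]).exists()]
    if missing:
        raise MissingInputError(
            "missing required inputs: " + ", ".join(sorted(missing)))

    digests = {k: _digest(v) for k, v in sorted(inputs.items())
               if Path(v).exists()}
    manifest = RunManifest(config=config.to_dict(), input_digests=digests,
                           version=__version__)

    variants = read_annotated_vcf(inputs["vcf"])
    pedigree = read_pedigree(inputs["ped"])
    cnvs = read_cnv_table(inputs["cnv"])
    phenotypes = read_phenotype_table(inputs["phenotypes"])
    gene_resource = read_gene_resource_table(inputs["gene_resources"])
    evidence_store = CuratedEvidence()
    if inputs.get("curated_evidence"):
        evidence_store = read_curated_evidence(inputs["curated_evidence"])
    external_phase = None
    if inputs.get("external_phase"):
        external_phase = read_external_phase(inputs["external_phase"])
    gene_model = None
    if inputs.get("gene_model"):
        gene_model = read_gene_model(inputs["gene_model"])
    manifest.stage_counts["ingest"] = {
        "variants": len(variants), "cnvs": len(cnvs),
        "samples": len(pedigree.members)}
    log.info("ingest: %d variants, %d CNV calls, %d samples",
             len(variants), len(cnvs), len(pedigree.members))

    batch_map = {p.sample_id: p.batch_id for p in phenotypes
                 if p.batch_id is not None}
    # parents inherit a batch from joint calling; default them to a
    # parental batch when the phenotype table only covers probands
    for m in pedigree.members:
        batch_map.setdefault(m.sample_id, "parental")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        surviving = batch_allele_filter(variants, batch_map, config)
    manifest.stage_counts["batch_filter"] = {
        "in": len(variants), "out": len(surviving),
        "filtered": len(variants) - len(surviving)}
    log.info("batch filter: %d -> %d", len(variants), len(surviving))

    cnv_rare = cnv_rare_filter(cnvs, config)
    cnv_evidence = cnv_prioritize(cnv_rare, gene_resource, gene_model)
    prioritized_cnvs = [e.cnv for e in cnv_evidence if e.prioritized]
    manifest.stage_counts["cnv_tracks"] = {
        "in": len(cnvs), "rare": len(cnv_rare),
        "prioritized": len(prioritized_cnvs)}

    findings: list[ClassifiedFinding] = []
    all_verdicts: dict = {}
    flagged: dict = {}
    probands = sorted(pedigree.probands, key=lambda m: m.sample_id)
    for p in probands:
        pid = p.sample_id
        try:
            verdicts = prioritize_proband(
                pid, surviving, pedigree, gene_resource, config,
                cnv_calls=cnvs, external_phase=external_phase)
            all_verdicts[pid] = verdicts
            for key, vd in sorted(verdicts.items()):
                if not vd.tracks_passed:
                    continue
                label = assign_inheritance(vd.variant, pedigree, pid)
                findings.append(classify_variant(
                    vd.variant, vd, label, gene_resource, evidence_store,
                    pid, _parent_affected(pedigree, pid, label), config))
            for cnv in prioritized_cnvs:
                if not cnv.genotype_of(pid).carries_alt:
                    continue
                label = assign_inheritance(cnv, pedigree, pid)
                findings.append(classify_variant(
                    cnv, None, label, gene_resource, evidence_store,
                    pid, _parent_affected(pedigree, pid, label), config))
        except Exception as exc:  # noqa: BLE001 - per-individual isolation
            flagged[pid] = str(exc)
            log.error("individual %s flagged: %s", pid, exc)
    manifest.stage_counts["classification"] = {
        "findings": len(findings), "flagged": len(flagged)}

    diagnosed = {f.case_id for f in findings
                 if f.clinical_significance in ("causative", "risk_factor")}

    vus_ids = set()
    for p in probands:
        pid = p.sample_id
        if pid in diagnosed or pid in flagged:
            continue
        for v in surviving:
            if v.genotype_of(pid).carries_alt and intolerant_gene_vus(
                    v, gene_resource, False, config):
                vus_ids.add(pid)
                break
    manifest.stage_counts["vus_track"] = {"individuals": len(vus_ids)}

    mech = {}
    by_case: dict[str, list] = {}
    for f in findings:
        if f.clinical_significance in ("causative", "risk_factor"):
            by_case.setdefault(f.case_id, []).append(f)
    for cid, fs in by_case.items():
        primary = next((f for f in fs
                        if f.clinical_significance == "causative"), fs[0])
        cnv_findings = [f for f in fs if f.is_cnv]
        mech[cid] = "cnv" if cnv_findings else _mechanism_of(primary,
                                                             gene_resource)

    summary = yield_summary(
        findings, [p.sample_id for p in probands],
        mechanism_map=mech, vus_intolerant_ids=vus_ids)
    manifest.stage_counts["stats"] = {"diagnosed": summary.n_diagnosed}

    return PipelineResult(
        findings=findings, verdicts=all_verdicts, diagnosed_ids=diagnosed,
        vus_intolerant_ids=vus_ids, summary=summary, manifest=manifest,
        flagged_individuals=flagged)


def _parent_affected(pedigree, proband_id, label) -> bool:
    father, mother = pedigree.parents_of(proband_id)
    if label.value == "maternal" and mother is not None:
        return mother.affected
    if label.value == "paternal" and father is not None:
        return father.affected
    return False


def render_summary(summary: Optional[YieldSummary],
                   stat_results=()) -> tuple[str, dict]:
    """Human-readable yield report and its machine-readable JSON twin."""
    if summary is None or summary.n_cohort == 0:
        return "diagnostic yield: n/a (empty cohort)\n", {"yield": None}
    lines = [
        f"cohort size: {summary.n_cohort}",
        f"diagnosed (causative or risk factor): "
        f"{summary.n_diagnosed}/{summary.n_cohort} "
        f"({pct(summary.n_diagnosed, summary.n_cohort)}%)",
        f"  CNV diagnoses: {summary.n_cnv_diagnosed}/{summary.n_cohort} "
        f"({pct(summary.n_cnv_diagnosed, summary.n_cohort)}%)",
        f"  SNV/indel diagnoses: {summary.n_snv_diagnosed}/"
        f"{summary.n_cohort} "
        f"({pct(summary.n_snv_diagnosed, summary.n_cohort)}%)",
        f"  causative: {summary.n_causative}; "
        f"risk factor: {summary.n_risk_factor}",
        f"intolerant-gene VUS individuals: {summary.n_vus_intolerant}/"
        f"{summary.n_cohort} "
        f"({pct(summary.n_vus_intolerant, summary.n_cohort)}%)",
    ]
    if summary.n_diagnosed:
        lines.append(
            f"  autosomal dominant mechanism: "
            f"{summary.n_autosomal_dominant}/{summary.n_diagnosed} "
            f"({pct(summary.n_autosomal_dominant, summary.n_diagnosed)}%)")
        for g, k in sorted(summary.aetiology_counts.items()):
            lines.append(f"  aetiology {g}: {k}/{summary.n_diagnosed} "
                         f"({pct(k, summary.n_diagnosed)}%)")
    for r in stat_results:
        ci = ""
        if r.ci_low is not None:
            ci = f" (95% CI {r.ci_low:.2f}-{r.ci_high:.2f})"
        lines.append(f"{r.name}: {r.estimate:.2f}{ci}, p={r.p_value:.3g}")
    text = "\n".join(lines) + "\n"
    payload = {
        "counts": {
            "n_cohort": summary.n_cohort,
            "n_diagnosed": summary.n_diagnosed,
            "n_cnv_diagnosed": summary.n_cnv_diagnosed,
            "n_snv_diagnosed": summary.n_snv_diagnosed,
            "n_causative": summary.n_causative,
            "n_risk_factor": summary.n_risk_factor,
            "n_vus_intolerant": summary.n_vus_intolerant,
            "n_autosomal_dominant": summary.n_autosomal_dominant,
            "aetiology": dict(sorted(summary.aetiology_counts.items())),
            "mechanism": dict(sorted(summary.mechanism_counts.items())),
        },
        "percentages": summary.percentages(),
        "stats": [
            {"name": r.name, "estimate": r.estimate, "p_value": r.p_value,
             "ci_low": r.ci_low, "ci_high": r.ci_high, "df": r.df}
            for r in stat_results
        ],
    }
    return text, payload
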