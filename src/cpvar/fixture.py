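"""Packaged transcription of the study's published variant tables.

The packaged data files are a transcription of the published summary
tables of the 150-proband cerebral palsy genome-sequencing cohort: the
causative pathogenic/likely-pathogenic findings, the risk-factor /
uncertain / incidental findings, the aetiology gene groupings and the
cohort composition. Per-variant curated ACMG evidence-tag sets are
synthetic stand-ins generated deterministically from the printed class,
consequence and population frequency (the study's real evidence lives in
an unpublished supplementary table); they are constructed so that the
published ACMG combining rules reproduce each printed class.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from .io import gene_resources_from_rows
from .types import GeneResourceTable, LOF_CONSEQUENCES

_DATA_FILES = ("reported_variants.tsv", "reported_genes.tsv",
               "cohort_composition.json")


class FixtureChecksumError(RuntimeError):
    pass


@dataclass
class FixtureVariant:
    """One transcribed row of the published variant tables."""

    case_id: str
    group: str                    # individual's table section
    genes: tuple
    variant: str
    variant_class: str
    consequence: str
    inheritance: str
    pop_freq: Optional[float]
    cadd: Optional[float]
    acmg_class: str               # printed 5-tier class (or risk_factor/modifier)
    clinical_significance: str
    mechanism: Optional[str]
    risk_allele: bool
    primary: bool
    curated_tags: frozenset = field(default=frozenset())

    @property
    def is_cnv(self) -> bool:
        return self.variant_class.startswith("CNV")

    @property
    def phenotype_fit(self) -> str:
        """Curated phenotype-fit level implied by the printed significance."""
        return {"causative": "full", "risk_factor": "partial",
                "incidental": "none"}.get(self.clinical_significance,
                                          "unknown")


def synthesize_curated_tags(acmg_class: str, consequence: str,
                            variant_class: str,
                            pop_freq: Optional[float]) -> frozenset:
    """Deterministic curated evidence tags reproducing a printed class.

    Loss-of-function consequences (and whole-gene deletions) receive PVS1;
    others receive strong functional/same-residue evidence. The moderate
    tag is PM2 (absent/ultra-rare) when the printed frequency supports it,
    else PM1 (domain evidence).
    """
    lof = consequence in LOF_CONSEQUENCES or variant_class == "CNV_del"
    pm = "PM2" if (pop_freq is None or pop_freq < 1.0e-4) else "PM1"
    if acmg_class == "pathogenic":
        return frozenset({"PVS1", "PS3", pm} if lof else {"PS1", "PS3", pm})
    if acmg_class == "likely_pathogenic":
        return frozenset({"PVS1", pm} if lof else {"PS3", pm})
    return frozenset()


@dataclass
class FixtureTables:
    variants: list[FixtureVariant]
    gene_resources: GeneResourceTable
    composition: dict

    # ---- individual-level groupings -------------------------------------
    @property
    def causative_ids(self) -> set:
        return {v.case_id for v in self.variants if v.group == "causative"}

    @property
    def risk_factor_ids(self) -> set:
        return {v.case_id for v in self.variants if v.group == "risk_factor"}

    @property
    def diagnosed_ids(self) -> set:
        return self.causative_ids | self.risk_factor_ids

    @property
    def uncertain_ids(self) -> set:
        """Individuals with >=1 P/LP finding of uncertain significance and
        no causative finding (the published count of ten)."""
        ids = {v.case_id for v in self.variants
               if v.clinical_significance == "uncertain"}
        return ids - self.causative_ids

    @property
    def incidental_ids(self) -> set:
        return {v.case_id for v in self.variants if v.group == "incidental"}

    @property
    def cnv_carrier_ids(self) -> set:
        """Diagnosed individuals whose reportable finding includes a CNV."""
        return {v.case_id for v in self.variants
                if v.is_cnv and v.case_id in self.diagnosed_ids}

    def variants_of(self, case_id: str) -> list[FixtureVariant]:
        return [v for v in self.variants if v.case_id == case_id]

    def primary_of(self, case_id: str) -> FixtureVariant:
        return next(v for v in self.variants
                    if v.case_id == case_id and v.primary)

    def aetiology_set(self, group: str) -> set:
        return {g for g in self.gene_resources.genes()
                if self.gene_resources.get(g).aetiology == group}


def _data_text(name: str) -> str:
    return resources.files("cpvar.data").joinpath(name).read_text()


def _verify_checksums() -> None:
    expected = {}
    for line in _data_text("CHECKSUMS").splitlines():
        if line.strip():
            digest, name = line.split()
            expected[name] = digest
    for name in _DATA_FILES:
        actual = hashlib.sha256(_data_text(name).encode()).hexdigest()
        if expected.get(name) != actual:
            raise FixtureChecksumError(
                f"packaged fixture file {name!r} failed its checksum")


def _opt_float(raw: str) -> Optional[float]:
    return None if raw in ("NA", "", ".") else float(raw)


def load_fixture(verify_checksum: bool = True) -> FixtureTables:
    """Load the packaged transcription of the published cohort tables."""
    if verify_checksum:
        _verify_checksums()
    variants = []
    for row in csv.DictReader(_data_text("reported_variants.tsv").splitlines(),
                              delimiter="\t"):
        pop_freq = _opt_float(row["pop_freq"])
        variants.append(FixtureVariant(
            case_id=row["case_id"], group=row["group"],
            genes=tuple(row["genes"].split(",")),
            variant=row["variant"], variant_class=row["variant_class"],
            consequence=row["consequence"], inheritance=row["inheritance"],
            pop_freq=pop_freq, cadd=_opt_float(row["cadd"]),
            acmg_class=row["acmg_class"],
            clinical_significance=row["clinical_significance"],
            mechanism=None if row["mechanism"] == "NA" else row["mechanism"],
            risk_allele=row["risk_allele"] == "1",
            primary=row["primary"] == "1",
            curated_tags=synthesize_curated_tags(
                row["acmg_class"], row["consequence"], row["variant_class"],
                pop_freq),
        ))
    gene_resources = gene_resources_from_rows(csv.DictReader(
        _data_text("reported_genes.tsv").splitlines(), delimiter="\t"))
    composition = json.loads(_data_text("cohort_composition.json"))
    return FixtureTables(variants=variants, gene_resources=gene_resources,
                        composition=composition)


def classify_fixture(tables: FixtureTables):
    """Run the classification engine over the transcribed variant rows.

    Returns (findings, mechanism_map): one classified finding per row —
    combining the curated tag set, applying the penetrance-downgrade
    policy (all sampled parents were unaffected) and assigning clinical
    significance and aetiology — plus the per-individual mechanism labels
    of the primary findings.
    """
    from .acmg import (ACMGEvidence, apply_penetrance_downgrade,
                       assign_aetiology, assign_clinical_significance,
                       combine_acmg, ClassifiedFinding)
    findings = []
    mechanisms = {}
    for row in tables.variants:
        ev = ACMGEvidence()
        for tag in sorted(row.curated_tags):
            ev.add(tag, "curated")
        finding = ClassifiedFinding(
            variant_keys=(row.variant,), case_id=row.case_id,
            genes=row.genes, acmg_class=combine_acmg(ev), evidence=ev,
            is_cnv=row.is_cnv)
        finding.trace.append(f"curated tags {sorted(ev.tags)}")
        finding = apply_penetrance_downgrade(
            finding, row.inheritance, parent_affected=False,
            gene_resource=tables.gene_resources)
        finding = assign_clinical_significance(
            finding, row.phenotype_fit, row.risk_allele)
        finding = assign_aetiology(finding, tables.gene_resources)
        findings.append(finding)
        if row.primary and row.mechanism:
            mechanisms[row.case_id] = row.mechanism
    return findings, mechanisms


def fixture_cohort_ids(tables: FixtureTables) -> list[str]:
    """All 150 proband identifiers: reported cases plus undiagnosed filler."""
    reported = sorted({v.case_id for v in tables.variants})
    n_filler = tables.composition["n_cohort"] - len(reported)
    return reported + [f"U{i + 1:03d}" for i in range(n_filler)]
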