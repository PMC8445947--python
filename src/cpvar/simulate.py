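"""Synthetic cohort generator with known ground truth.

Emulates the study conditions: 150 probands (18 trios, 76 duos, 56
singletons; 93 male / 57 female), 37 planted reportable findings of which
7 are CNVs, joint-calling batches of >= 40 samples, and a logistic link
between the number of neurodevelopmental comorbidities and carrying a
reportable finding (default odds ratio 1.68). Variants live on two
synthetic contigs with a packaged ~60-gene toy gene model — the pipeline
only consumes annotations, never sequence.

Inheritance truth is generated first and genotypes second, so Mendelian
consistency is guaranteed except for deliberately planted de novo and
Mendelian-conflict cases. Background annotation values are drawn from
mixtures placing mass on both sides of every filter threshold so the
track predicates are exercised at their boundaries.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.stats import binom

from .config import FilterConfig
from .io import (
    CuratedEvidence,
    write_annotated_vcf,
    write_cnv_table,
    write_curated_evidence,
    write_gene_resource_table,
    write_pedigree,
    write_phenotype_table,
)
from .types import (
    AnnotatedVariant,
    AnnotationBundle,
    GenotypeCall,
    GeneResource,
    GeneResourceTable,
    PedigreeGraph,
    PedigreeMember,
    SamplePhenotype,
    Zygosity,
    IMAGING_CLASSES,
)


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_probands: int = 150
    n_trios: int = 18
    n_duos_maternal: int = 63   # printed duo split (62/13) does not sum to 76
    n_duos_paternal: int = 13
    n_singletons: int = 56
    n_male: int = 93
    n_diagnosed: int = 37
    n_cnv_diagnosed: int = 7
    n_risk_factor: int = 9
    n_trio_diagnosed: int = 7
    comorbidity_or: float = 1.68
    comorbidity_base_rate: float = 0.35   # per-flag prior rate
    n_comorbidity_missing: int = 13
    batch_size: int = 50
    background_variants_per_proband: int = 8
    de_novo_background_rate: float = 0.02
    mendelian_conflict_rate: float = 0.01

    def __post_init__(self):
        ped_sum = (self.n_trios + self.n_duos_maternal
                   + self.n_duos_paternal + self.n_singletons)
        if ped_sum != self.n_probands:
            raise ValueError(
                f"pedigree mix sums to {ped_sum}, not {self.n_probands}")
        if self.n_cnv_diagnosed > self.n_diagnosed:
            raise ValueError("CNV share exceeds the diagnosis count")
        if self.n_diagnosed > self.n_probands:
            raise ValueError("diagnosis count exceeds the cohort size")
        if self.n_male > self.n_probands:
            raise ValueError("male count exceeds the cohort size")
        if self.n_trio_diagnosed > min(self.n_trios, self.n_diagnosed):
            raise ValueError("trio diagnoses exceed the trio count")
        if self.n_risk_factor > self.n_diagnosed:
            raise ValueError("risk-factor count exceeds the diagnosis count")
        if self.n_comorbidity_missing > self.n_probands:
            raise ValueError("more missing-comorbidity individuals than probands")


@dataclass
class TruthRecord:
    case_id: str
    gene: str
    variant_keys: list
    category: str        # dominant | recessive_hom | compound_het |
    #                      clinvar | cnv
    acmg_class: str
    clinical_significance: str
    aetiology: Optional[str]
    inheritance: str


@dataclass
class TruthSet:
    diagnosed: dict = field(default_factory=dict)   # case_id -> TruthRecord
    comorbidity_alpha: float = 0.0
    comorbidity_beta: float = 0.0

    @property
    def diagnosed_ids(self) -> set:
        return set(self.diagnosed)

    def to_json(self) -> dict:
        return {
            "comorbidity_alpha": self.comorbidity_alpha,
            "comorbidity_beta": self.comorbidity_beta,
            "diagnosed": {cid: asdict(rec)
                          for cid, rec in sorted(self.diagnosed.items())},
        }


def load_toy_genes() -> list[dict]:
    text = resources.files("cpvar.data").joinpath("toy_genes.tsv").read_text()
    out = []
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        out.append({"gene": row["gene"], "contig": row["contig"],
                    "coding_start": int(row["coding_start"]),
                    "coding_end": int(row["coding_end"])})
    return out


# gene-pool roles within the 60-gene toy model
_DOMINANT_POOL = [f"GENE{i:02d}" for i in range(1, 25)]
_AR_POOL = [f"GENE{i:02d}" for i in range(25, 29)]
_CLINVAR_POOL = ["GENE29", "GENE30"]
_CNV_POOL = [f"GENE{i:02d}" for i in range(31, 38)]
_INTOLERANT_POOL = [f"GENE{i:02d}" for i in range(38, 46)]
_NEUTRAL_POOL = [f"GENE{i:02d}" for i in range(46, 61)]

_AETIOLOGY_FOR = {}
for _i, _g in enumerate(_DOMINANT_POOL):
    _AETIOLOGY_FOR[_g] = ("stroke_cardiovascular" if _i < 8
                          else "HSP" if _i < 12 else "NDD")
for _g in _AR_POOL + _CNV_POOL:
    _AETIOLOGY_FOR[_g] = "NDD"
for _g in _CLINVAR_POOL:
    _AETIOLOGY_FOR[_g] = "stroke_cardiovascular"


def synthetic_gene_resources() -> GeneResourceTable:
    """Per-gene resources matched to each pool's role in the simulation."""
    rows = []
    for g in _DOMINANT_POOL:
        rows.append(GeneResource(
            gene=g, panels=frozenset({"CP", "DDG2P"}), missense_z=3.0,
            lof_oe=0.1, inheritance_mode="AD", penetrance_caveat=True,
            lof_mechanism=True, omim=True, aetiology=_AETIOLOGY_FOR[g]))
    for g in _AR_POOL:
        rows.append(GeneResource(
            gene=g, panels=frozenset({"DDG2P"}), missense_z=0.5, lof_oe=0.3,
            inheritance_mode="AR", lof_mechanism=True, omim=True,
            aetiology=_AETIOLOGY_FOR[g]))
    for g in _CLINVAR_POOL:
        rows.append(GeneResource(
            gene=g, panels=frozenset({"CP"}), inheritance_mode="AD",
            penetrance_caveat=True, omim=True,
            aetiology=_AETIOLOGY_FOR[g]))
    for g in _CNV_POOL:
        rows.append(GeneResource(
            gene=g, panels=frozenset({"CP"}), lof_oe=0.2,
            inheritance_mode="AD", penetrance_caveat=True,
            lof_mechanism=True, omim=True, aetiology=_AETIOLOGY_FOR[g]))
    for g in _INTOLERANT_POOL:
        rows.append(GeneResource(
            gene=g, missense_z=2.5, lof_oe=0.4, inheritance_mode="unknown"))
    for g in _NEUTRAL_POOL:
        rows.append(GeneResource(
            gene=g, missense_z=0.5, lof_oe=0.9, inheritance_mode="unknown"))
    return GeneResourceTable(rows)


# ------------------------------------------------------------- pedigree

def build_pedigree(config: SimConfig, rng) -> PedigreeGraph:
    sexes = np.array(["male"] * config.n_male
                     + ["female"] * (config.n_probands - config.n_male))
    rng.shuffle(sexes)
    members = []
    idx = 0
    for i in range(config.n_probands):
        fam = f"F{i + 1:03d}"
        pid = f"P{i + 1:03d}"
        kind_bounds = (config.n_trios,
                       config.n_trios + config.n_duos_maternal,
                       config.n_trios + config.n_duos_maternal
                       + config.n_duos_paternal)
        if i < kind_bounds[0]:
            kind = "trio"
        elif i < kind_bounds[1]:
            kind = "duo_maternal"
        elif i < kind_bounds[2]:
            kind = "duo_paternal"
        else:
            kind = "singleton"
        mother_id = f"M{i + 1:03d}" if kind in ("trio", "duo_maternal") else None
        father_id = f"D{i + 1:03d}" if kind in ("trio", "duo_paternal") else None
        members.append(PedigreeMember(
            sample_id=pid, family_id=fam, father_id=father_id,
            mother_id=mother_id, sex=str(sexes[idx]), affected=True,
            role="proband"))
        idx += 1
        if mother_id:
            members.append(PedigreeMember(
                sample_id=mother_id, family_id=fam, father_id=None,
                mother_id=None, sex="female", affected=False, role="mother"))
        if father_id:
            members.append(PedigreeMember(
                sample_id=father_id, family_id=fam, father_id=None,
                mother_id=None, sex="male", affected=False, role="father"))
    return PedigreeGraph(members)


def batch_map_for(pedigree: PedigreeGraph, config: SimConfig) -> dict:
    """Probands batch together (joint-called first); parents separately."""
    out = {}
    probands = sorted(p.sample_id for p in pedigree.probands)
    for i, pid in enumerate(probands):
        out[pid] = f"B{i // config.batch_size + 1}"
    parents = sorted(m.sample_id for m in pedigree.members
                     if m.role in ("mother", "father"))
    for i, pid in enumerate(parents):
        out[pid] = f"PB{i // max(config.batch_size, 40) + 1}"
    return out


# ----------------------------------------------------------- comorbidity

def comorbidity_alpha(beta: float, base_rate: float,
                      target_rate: float) -> float:
    """Intercept making the marginal diagnosis rate hit target_rate under
    a Binomial(3, base_rate) comorbidity-count prior."""
    prior = binom.pmf(np.arange(4), 3, base_rate)

    def marginal(alpha):
        return float(prior @ (1.0 / (1.0 + np.exp(-(alpha + beta
                                                    * np.arange(4))))))

    if target_rate <= 0.0:
        return -20.0
    if target_rate >= 1.0:
        return 20.0
    return brentq(lambda a: marginal(a) - target_rate, -20.0, 20.0)


def draw_comorbidity_counts(rng, diagnosed, odds_ratio: float,
                            base_rate: float) -> np.ndarray:
    """Draw per-individual comorbidity counts (0-3) given diagnosis status.

    Counts are drawn from the Bayes-consistent conditional P(c | d) of a
    logistic model logit P(d | c) = alpha + log(OR) * c with a
    Binomial(3, base_rate) prior on c, so a logistic regression of
    diagnosis on count recovers log(OR).
    """
    diagnosed = np.asarray(diagnosed, dtype=bool)
    beta = np.log(odds_ratio)
    alpha = comorbidity_alpha(beta, base_rate, float(diagnosed.mean()))
    c = np.arange(4)
    prior = binom.pmf(c, 3, base_rate)
    p_d = 1.0 / (1.0 + np.exp(-(alpha + beta * c)))
    post1 = prior * p_d
    post1 /= post1.sum()
    post0 = prior * (1 - p_d)
    post0 /= post0.sum()
    out = np.empty(diagnosed.size, dtype=int)
    for i, d in enumerate(diagnosed):
        out[i] = rng.choice(c, p=post1 if d else post0)
    return out


# ------------------------------------------------------ variant planting

def _family_genotypes(pedigree, proband_id, proband_z, origin) -> list:
    """Genotype calls for the proband's family under a chosen origin.

    origin: de_novo | maternal | paternal | biparental | none.
    Present family members are always explicitly genotyped (hom_ref when
    non-carrier) — joint calling reports reference calls, and de novo
    labelling requires them.
    """
    father, mother = pedigree.parents_of(proband_id)
    calls = [GenotypeCall(proband_id, proband_z)]
    if mother is not None:
        z = Zygosity.HET if origin in ("maternal", "biparental") \
            else Zygosity.HOM_REF
        calls.append(GenotypeCall(mother.sample_id, z))
    if father is not None:
        z = Zygosity.HET if origin in ("paternal", "biparental") \
            else Zygosity.HOM_REF
        calls.append(GenotypeCall(father.sample_id, z))
    return calls


_BASES = ("A", "C", "G", "T")


def _snv_at(gene_info, offset, rng_like_index, genotypes, **ann_kw):
    pos = gene_info["coding_start"] + offset
    ref = _BASES[pos % 4]
    alt = _BASES[(pos + 1 + rng_like_index) % 4]
    if alt == ref:
        alt = _BASES[(pos + 2) % 4]
    ann = AnnotationBundle(gene_symbols=frozenset({gene_info["gene"]}),
                           **ann_kw)
    return AnnotatedVariant(
        contig=gene_info["contig"], position=pos, ref=ref, alt=alt,
        variant_class="SNV", annotations=ann, genotypes=genotypes)


_DELETERIOUS = dict(sift="D", polyphen2_hvar="D", mutation_taster="D",
                    metasvm="D", gerp_rs=5.2)
_BENIGN_INSILICO = dict(sift="T", polyphen2_hvar="B", mutation_taster="N",
                        metasvm="T", gerp_rs=-1.0)


def plant_findings(config: SimConfig, pedigree: PedigreeGraph, rng,
                   genes_by_name: dict) -> tuple[list, list, CuratedEvidence,
                                                 TruthSet]:
    """Plant the reportable findings and return (snvs, cnvs, evidence, truth).

    Category mix: n_cnv_diagnosed CNVs; 2 homozygous recessive; 2
    compound-het; 2 ClinVar-known (frequency above the rare-variant
    threshold, caught by the known-pathogenic track); the rest dominant
    rare-deleterious. The configured number of risk-factor individuals
    get partial phenotype fit among the dominant carriers.
    """
    probands = sorted(p.sample_id for p in pedigree.probands)
    trios = [p for p in probands if pedigree.parents_of(p)[0] is not None
             and pedigree.parents_of(p)[1] is not None]
    non_trios = [p for p in probands if p not in trios]
    n_trio_diag = min(config.n_trio_diagnosed, config.n_diagnosed)
    chosen_trios = [str(s) for s in rng.choice(trios, size=n_trio_diag,
                                               replace=False)]
    n_rest = config.n_diagnosed - n_trio_diag
    chosen_rest = [str(s) for s in rng.choice(non_trios, size=n_rest,
                                              replace=False)]
    diagnosed = chosen_trios + chosen_rest
    if not diagnosed:
        return [], [], CuratedEvidence(), TruthSet()

    # category mix: CNVs first, then up to two each of the recessive,
    # compound-het and ClinVar-track routes, the rest dominant
    categories = ["cnv"] * config.n_cnv_diagnosed
    for special in ("recessive_hom", "compound_het", "clinvar"):
        n = min(2, config.n_diagnosed - len(categories))
        categories += [special] * n
    categories += ["dominant"] * (config.n_diagnosed - len(categories))
    # keep one trio dominant and de novo (the study saw 1 confirmed de novo)
    categories = list(rng.permutation(categories))
    de_novo_case = None
    for idx, cid in enumerate(diagnosed):
        if cid in chosen_trios and categories[idx] == "dominant":
            de_novo_case = cid
            break
    if de_novo_case is None and chosen_trios:
        # force: swap a dominant slot onto the first trio
        first_trio_idx = diagnosed.index(chosen_trios[0])
        dom_idx = categories.index("dominant")
        categories[first_trio_idx], categories[dom_idx] = \
            "dominant", categories[first_trio_idx]
        de_novo_case = chosen_trios[0]

    snvs: list[AnnotatedVariant] = []
    cnvs: list[AnnotatedVariant] = []
    evidence = CuratedEvidence()
    truth = TruthSet()
    risk_quota = config.n_risk_factor

    pool_cursor = {"dominant": 0, "recessive": 0, "clinvar": 0, "cnv": 0}

    for idx, cid in enumerate(diagnosed):
        cat = categories[idx]
        father, mother = pedigree.parents_of(cid)
        has_mother, has_father = mother is not None, father is not None
        if cat == "dominant":
            gene = _DOMINANT_POOL[pool_cursor["dominant"]
                                  % len(_DOMINANT_POOL)]
            pool_cursor["dominant"] += 1
            gi = genes_by_name[gene]
            if cid == de_novo_case:
                origin = "de_novo"
            elif has_mother and has_father:
                origin = "maternal" if rng.random() < 0.5 else "paternal"
            elif has_mother:
                origin = "maternal"
            elif has_father:
                origin = "paternal"
            else:
                origin = "none"
            consequence = "nonsynonymous" if idx % 2 == 0 else "stopgain"
            v = _snv_at(gi, 10 + idx * 7, idx,
                        _family_genotypes(pedigree, cid, Zygosity.HET, origin),
                        gnomad_af=0.0, exac_af=0.0,
                        cadd_phred=float(24 + idx % 12),
                        consequence=consequence, **_DELETERIOUS)
            snvs.append(v)
            fit = "partial" if risk_quota > 0 else "full"
            if risk_quota > 0:
                risk_quota -= 1
            for tag in ("PS3", "PM2") + (("PVS1",)
                                         if consequence == "stopgain" else
                                         ("PS1",)):
                evidence.add(v.key, tag)
            evidence.add(v.key, f"phenotype_fit_{fit}")
            truth.diagnosed[cid] = TruthRecord(
                case_id=cid, gene=gene, variant_keys=[v.key],
                category="dominant", acmg_class="pathogenic",
                clinical_significance=("risk_factor" if fit == "partial"
                                       else "causative"),
                aetiology=_AETIOLOGY_FOR[gene], inheritance=origin)
        elif cat == "recessive_hom":
            gene = _AR_POOL[pool_cursor["recessive"] % len(_AR_POOL)]
            pool_cursor["recessive"] += 1
            gi = genes_by_name[gene]
            origin = "biparental" if (has_mother or has_father) else "none"
            v = _snv_at(gi, 500 + idx * 3, idx,
                        _family_genotypes(pedigree, cid, Zygosity.HOM_ALT,
                                          "biparental"),
                        gnomad_af=5.0e-3, exac_af=4.0e-3,
                        cadd_phred=25.0, consequence="nonsynonymous",
                        **_DELETERIOUS)
            snvs.append(v)
            for tag in ("PS3", "PM3", "PM1"):
                evidence.add(v.key, tag)
            evidence.add(v.key, "phenotype_fit_full")
            truth.diagnosed[cid] = TruthRecord(
                case_id=cid, gene=gene, variant_keys=[v.key],
                category="recessive_hom", acmg_class="likely_pathogenic",
                clinical_significance="causative",
                aetiology=_AETIOLOGY_FOR[gene], inheritance=origin)
        elif cat == "compound_het":
            gene = _AR_POOL[pool_cursor["recessive"] % len(_AR_POOL)]
            pool_cursor["recessive"] += 1
            gi = genes_by_name[gene]
            oa = "maternal" if has_mother else "none"
            ob = "paternal" if has_father else "none"
            va = _snv_at(gi, 700 + idx * 5, idx,
                         _family_genotypes(pedigree, cid, Zygosity.HET, oa),
                         gnomad_af=2.0e-3, exac_af=0.0, cadd_phred=27.0,
                         consequence="nonsynonymous", **_DELETERIOUS)
            vb = _snv_at(gi, 900 + idx * 5, idx + 1,
                         _family_genotypes(pedigree, cid, Zygosity.HET, ob),
                         gnomad_af=0.0, exac_af=1.0e-3, cadd_phred=31.0,
                         consequence="stopgain", **_DELETERIOUS)
            snvs.extend([va, vb])
            for v in (va, vb):
                for tag in ("PS3", "PM3", "PM1"):
                    evidence.add(v.key, tag)
                evidence.add(v.key, "phenotype_fit_full")
            truth.diagnosed[cid] = TruthRecord(
                case_id=cid, gene=gene, variant_keys=[va.key, vb.key],
                category="compound_het", acmg_class="likely_pathogenic",
                clinical_significance="causative",
                aetiology=_AETIOLOGY_FOR[gene],
                inheritance="biparental" if (has_mother and has_father)
                else "unknown")
        elif cat == "clinvar":
            gene = _CLINVAR_POOL[pool_cursor["clinvar"] % len(_CLINVAR_POOL)]
            pool_cursor["clinvar"] += 1
            gi = genes_by_name[gene]
            origin = ("maternal" if has_mother else
                      "paternal" if has_father else "none")
            v = _snv_at(gi, 1200 + idx * 3, idx,
                        _family_genotypes(pedigree, cid, Zygosity.HET, origin),
                        gnomad_af=8.0e-3, exac_af=8.0e-3,
                        consequence="noncoding",
                        clinvar_terms=frozenset({"Pathogenic"}))
            snvs.append(v)
            for tag in ("PS3", "PS4", "PM1"):
                evidence.add(v.key, tag)
            evidence.add(v.key, "phenotype_fit_full")
            truth.diagnosed[cid] = TruthRecord(
                case_id=cid, gene=gene, variant_keys=[v.key],
                category="clinvar", acmg_class="pathogenic",
                clinical_significance="causative",
                aetiology=_AETIOLOGY_FOR[gene], inheritance=origin)
        else:  # cnv
            gene = _CNV_POOL[pool_cursor["cnv"] % len(_CNV_POOL)]
            pool_cursor["cnv"] += 1
            gi = genes_by_name[gene]
            del_dup = "CNV_del" if pool_cursor["cnv"] % 2 else "CNV_dup"
            start = gi["coding_start"] - 2_000 + (idx % 5) * 137
            end = gi["coding_end"] + 3_000
            c = AnnotatedVariant(
                contig=gi["contig"], position=start, ref="N",
                alt="<DEL>" if del_dup == "CNV_del" else "<DUP>",
                variant_class=del_dup, span_end=end,
                annotations=AnnotationBundle(
                    mgrb_af=0.0, gene_symbols=frozenset({gene}),
                    consequence="cnv"),
                genotypes=[GenotypeCall(cid, Zygosity.HET)])
            cnvs.append(c)
            tags = ("PVS1", "PS3", "PM2") if del_dup == "CNV_del" \
                else ("PS1", "PS3", "PM2")
            for tag in tags:
                evidence.add(c.key, tag)
            evidence.add(c.key, "phenotype_fit_full")
            truth.diagnosed[cid] = TruthRecord(
                case_id=cid, gene=gene, variant_keys=[c.key],
                category="cnv", acmg_class="pathogenic",
                clinical_significance="causative",
                aetiology=_AETIOLOGY_FOR[gene], inheritance="unknown")
    return snvs, cnvs, evidence, truth


# ----------------------------------------------------- background layer

_FREQ_MIX = (0.0, 2.0e-5, 9.0e-5, 1.1e-4, 5.0e-4, 5.0e-3, 2.0e-2)
_FREQ_W = (0.25, 0.15, 0.1, 0.1, 0.15, 0.15, 0.1)
_CSQ_MIX = ("nonsynonymous", "stopgain", "frameshift", "splicing",
            "synonymous", "noncoding")
_CSQ_W = (0.4, 0.08, 0.07, 0.05, 0.2, 0.2)


def background_variants(config: SimConfig, pedigree: PedigreeGraph, rng,
                        toy_genes: list) -> list[AnnotatedVariant]:
    """Per-proband background variants straddling the filter thresholds."""
    out = []
    background_pool = toy_genes  # any gene can host background variation
    for p in sorted(pedigree.probands, key=lambda m: m.sample_id):
        father, mother = pedigree.parents_of(p.sample_id)
        for j in range(config.background_variants_per_proband):
            gi = background_pool[int(rng.integers(len(background_pool)))]
            offset = int(rng.integers(2_000, 9_000))
            freq = float(rng.choice(_FREQ_MIX, p=_FREQ_W))
            cadd = float(np.round(rng.normal(20.0, 5.0), 1))
            cadd = max(cadd, 0.1)
            csq = str(rng.choice(_CSQ_MIX, p=_CSQ_W))
            deleterious = rng.random() < 0.5
            insilico = _DELETERIOUS if deleterious else _BENIGN_INSILICO
            u = rng.random()
            if u < config.mendelian_conflict_rate and (mother or father):
                origin, zyg = "conflict", Zygosity.HOM_ALT
            elif u < (config.mendelian_conflict_rate
                      + config.de_novo_background_rate):
                origin, zyg = "de_novo", Zygosity.HET
            else:
                zyg = Zygosity.HET
                choices = []
                if mother is not None:
                    choices.append("maternal")
                if father is not None:
                    choices.append("paternal")
                origin = (str(rng.choice(choices)) if choices else "none")
            genotypes = _family_genotypes(
                pedigree, p.sample_id, zyg,
                "none" if origin in ("conflict", "de_novo") else origin)
            v = _snv_at(gi, offset, j,
                        genotypes, gnomad_af=freq,
                        exac_af=None if rng.random() < 0.5 else freq,
                        cadd_phred=None if rng.random() < 0.1 else cadd,
                        consequence=csq, **insilico)
            out.append(v)
    return out


def shared_batch_variants(config: SimConfig, pedigree: PedigreeGraph,
                          batch_map: dict, rng,
                          toy_genes: list) -> list[AnnotatedVariant]:
    """Variants shared within a proband batch at allele counts 2 and 3,
    exercising both sides of the batch allele-count boundary."""
    by_batch: dict[str, list[str]] = {}
    for p in sorted(pedigree.probands, key=lambda m: m.sample_id):
        by_batch.setdefault(batch_map[p.sample_id], []).append(p.sample_id)
    out = []
    for bi, (batch, pids) in enumerate(sorted(by_batch.items())):
        for ac, count_variants in ((2, 2), (3, 2)):
            for k in range(count_variants):
                gi = toy_genes[(bi * 7 + k) % len(toy_genes)]
                carriers = pids[k * 4:k * 4 + ac]
                genotypes = [GenotypeCall(c, Zygosity.HET) for c in carriers]
                v = _snv_at(gi, 9_500 + bi * 29 + ac * 5 + k, bi + k,
                            genotypes, gnomad_af=0.0,
                            cadd_phred=26.0, consequence="nonsynonymous",
                            **_DELETERIOUS)
                out.append(v)
    return out


def background_cnvs(config: SimConfig, pedigree: PedigreeGraph, rng,
                    toy_genes: list) -> list[AnnotatedVariant]:
    """Non-reportable CNV calls: common, intergenic or failing detection."""
    out = []
    probands = sorted(p.sample_id for p in pedigree.probands)
    cases = [
        dict(af=0.02, genes=True, pass_flag=True),     # too common
        dict(af=0.0, genes=False, pass_flag=True),     # intergenic
        dict(af=0.0, genes=True, pass_flag=False),     # failed detection
        dict(af=0.009, genes=True, pass_flag=True),    # rare: survives rarity
    ]
    for i, case in enumerate(cases * 3):
        pid = probands[int(rng.integers(len(probands)))]
        gi = toy_genes[(i * 11) % len(toy_genes)]
        start = gi["coding_start"] - 500 + i * 91
        genes = frozenset({gi["gene"]}) if case["genes"] else frozenset()
        out.append(AnnotatedVariant(
            contig=gi["contig"], position=start, ref="N", alt="<DEL>",
            variant_class="CNV_del", span_end=start + 4_000,
            annotations=AnnotationBundle(
                mgrb_af=case["af"], gene_symbols=genes, consequence="cnv"),
            genotypes=[GenotypeCall(pid, Zygosity.HET)],
            pass_flag=case["pass_flag"]))
    return out


# ------------------------------------------------------------ phenotypes

def build_phenotypes(config: SimConfig, pedigree: PedigreeGraph,
                     batch_map: dict, truth: TruthSet, rng
                     ) -> list[SamplePhenotype]:
    probands = sorted(pedigree.probands, key=lambda m: m.sample_id)
    diagnosed = np.array([p.sample_id in truth.diagnosed for p in probands])
    counts = draw_comorbidity_counts(rng, diagnosed, config.comorbidity_or,
                                     config.comorbidity_base_rate)
    truth.comorbidity_beta = float(np.log(config.comorbidity_or))
    truth.comorbidity_alpha = float(comorbidity_alpha(
        truth.comorbidity_beta, config.comorbidity_base_rate,
        float(diagnosed.mean())))
    missing_idx = set(rng.choice(len(probands),
                                 size=config.n_comorbidity_missing,
                                 replace=False).tolist())
    out = []
    for i, p in enumerate(probands):
        ga = float(np.round(np.clip(rng.normal(38.0, 2.8), 24.0, 42.0), 1))
        centile = float(np.round(rng.uniform(1, 99), 1))
        imaging = str(rng.choice(IMAGING_CLASSES))
        if i in missing_idx:
            flags = (None, None, None)
        else:
            which = rng.permutation(3)[:counts[i]]
            flags = tuple(bool(k in which) for k in range(3))
        out.append(SamplePhenotype(
            sample_id=p.sample_id, sex=p.sex, gestational_age_weeks=ga,
            birth_weight_centile=centile, autism=flags[0],
            developmental_delay=flags[1], epilepsy=flags[2],
            imaging_class=imaging, batch_id=batch_map[p.sample_id]))
    return out


# ------------------------------------------------------------- generator

def generate_cohort(config: SimConfig, seed: int, outdir) -> TruthSet:
    """Write a complete synthetic cohort to ``outdir`` and return its truth.

    Emits cohort.vcf, cohort.ped, cnv_calls.tsv, phenotypes.tsv,
    gene_resources.tsv, curated_evidence.tsv and truth.json. Output is
    byte-identical for identical (config, seed).
    """
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    toy_genes = load_toy_genes()
    genes_by_name = {g["gene"]: g for g in toy_genes}

    pedigree = build_pedigree(config, rng)
    batches = batch_map_for(pedigree, config)
    snvs, cnvs, evidence, truth = plant_findings(config, pedigree, rng,
                                                 genes_by_name)
    snvs = snvs + background_variants(config, pedigree, rng, toy_genes) \
        + shared_batch_variants(config, pedigree, batches, rng, toy_genes)
    cnvs = cnvs + background_cnvs(config, pedigree, rng, toy_genes)
    cnvs.sort(key=lambda c: (c.contig, c.position, c.variant_class,
                             c.genotypes[0].sample_id))
    phenotypes = build_phenotypes(config, pedigree, batches, truth, rng)

    write_pedigree(outdir / "cohort.ped", pedigree)
    write_annotated_vcf(outdir / "cohort.vcf", snvs)
    write_cnv_table(outdir / "cnv_calls.tsv", cnvs)
    write_phenotype_table(outdir / "phenotypes.tsv", phenotypes)
    write_gene_resource_table(outdir / "gene_resources.tsv",
                              synthetic_gene_resources())
    write_curated_evidence(outdir / "curated_evidence.tsv", evidence)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth.to_json(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return truth


# --------------------------------------------------------- boundary suite

@dataclass
class BoundaryCase:
    name: str
    track: str        # filter1 | batch | vus_missense | vus_lof | cnv
    expected_pass: bool
    payload: dict


def boundary_suite(config: Optional[FilterConfig] = None) -> list[BoundaryCase]:
    """Deterministic threshold-boundary cases with expected verdicts.

    One case on each side of: the rare-variant frequency threshold
    (0.9e-4 / 1.1e-4), the CADD cut (19.9 / 20.1), the in-silico vote
    minimum (2 / 3 votes), the batch allele-count maximum (2 / 3), the
    constraint cuts (missense Z 1.9 / 2.1, LoF o/e 0.49 / 0.51) and the
    CNV population-frequency cut (0.9% / 1.1%).
    """
    config = config or FilterConfig()
    cases = [
        BoundaryCase("af_below", "filter1", True, dict(af=0.9e-4)),
        BoundaryCase("af_above", "filter1", False, dict(af=1.1e-4)),
        BoundaryCase("cadd_below", "filter1", False, dict(cadd=19.9)),
        BoundaryCase("cadd_above", "filter1", True, dict(cadd=20.1)),
        BoundaryCase("votes_2", "filter1", False, dict(votes=2)),
        BoundaryCase("votes_3", "filter1", True, dict(votes=3)),
        BoundaryCase("batch_ac_2", "batch", True, dict(ac=2)),
        BoundaryCase("batch_ac_3", "batch", False, dict(ac=3)),
        BoundaryCase("missense_z_19", "vus_missense", False, dict(z=1.9)),
        BoundaryCase("missense_z_21", "vus_missense", True, dict(z=2.1)),
        BoundaryCase("lof_oe_049", "vus_lof", True, dict(oe=0.49)),
        BoundaryCase("lof_oe_051", "vus_lof", False, dict(oe=0.51)),
        BoundaryCase("mgrb_009", "cnv", True, dict(af=0.009)),
        BoundaryCase("mgrb_011", "cnv", False, dict(af=0.011)),
    ]
    return cases


def evaluate_boundary_case(case: BoundaryCase,
                           config: Optional[FilterConfig] = None) -> bool:
    """Run one boundary case through the real filter implementations."""
    from .cnv_filters import cnv_rare_filter
    from .snv_filters import (batch_allele_filter, filter1_rare_deleterious,
                              intolerant_gene_vus, FilterVerdict)
    config = config or FilterConfig()
    p = case.payload
    resources = GeneResourceTable([
        GeneResource(gene="BGENE", panels=frozenset(),
                     missense_z=p.get("z"), lof_oe=p.get("oe"),
                     omim=True),
    ])
    if case.track == "filter1":
        n_votes = p.get("votes", 5)
        ann = dict(_DELETERIOUS)
        if n_votes < 5:
            benign_order = ["gerp_rs", "metasvm", "mutation_taster",
                           "polyphen2_hvar", "sift"]
            for f in benign_order[:5 - n_votes]:
                ann[f] = _BENIGN_INSILICO[f]
        v = AnnotatedVariant(
            contig="1", position=100, ref="A", alt="G", variant_class="SNV",
            annotations=AnnotationBundle(
                gnomad_af=p.get("af", 0.0), cadd_phred=p.get("cadd", 30.0),
                consequence="nonsynonymous",
                gene_symbols=frozenset({"BGENE"}), **ann),
            genotypes=[GenotypeCall("S1", Zygosity.HET)])
        verdict = FilterVerdict(v, "S1")
        return filter1_rare_deleterious(v, resources, config, verdict)
    if case.track == "batch":
        carriers = [GenotypeCall(f"S{i}", Zygosity.HET)
                    for i in range(p["ac"])]
        v = AnnotatedVariant(
            contig="1", position=100, ref="A", alt="G", variant_class="SNV",
            annotations=AnnotationBundle(consequence="nonsynonymous",
                                         gene_symbols=frozenset({"BGENE"})),
            genotypes=carriers)
        batch_map = {f"S{i}": "B1" for i in range(60)}
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            survivors = batch_allele_filter([v], batch_map, config)
        return bool(survivors)
    if case.track in ("vus_missense", "vus_lof"):
        csq = "nonsynonymous" if case.track == "vus_missense" else "stopgain"
        v = AnnotatedVariant(
            contig="1", position=100, ref="A", alt="G", variant_class="SNV",
            annotations=AnnotationBundle(
                gnomad_af=0.0, cadd_phred=28.0, consequence=csq,
                gene_symbols=frozenset({"BGENE"})),
            genotypes=[GenotypeCall("S1", Zygosity.HET)])
        return intolerant_gene_vus(v, resources, False, config)
    if case.track == "cnv":
        c = AnnotatedVariant(
            contig="1", position=100, ref="N", alt="<DEL>",
            variant_class="CNV_del", span_end=5_000,
            annotations=AnnotationBundle(
                mgrb_af=p["af"], gene_symbols=frozenset({"BGENE"}),
                consequence="cnv"),
            genotypes=[GenotypeCall("S1", Zygosity.HET)], pass_flag=True)
        return bool(cnv_rare_filter([c], config))
    raise ValueError(case.track)
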