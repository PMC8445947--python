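"""Readers and writers for the pipeline's external file formats.

Formats: annotated VCF 4.x (SNVs/indels, cyvcf2 reader / pysam writer),
6-column PED pedigrees, BED-like CNV call TSV (0-based half-open input,
converted to the internal 1-based inclusive convention on read), phenotype
TSV, gene-resource TSV, curated ACMG-evidence TSV and external phase TSV.

Readers never invent values: a missing INFO key or an ``NA`` cell becomes
``None`` (or an empty set), not a default.
"""

from __future__ import annotations

import csv
from typing import Optional

import cyvcf2
import pysam

from .config import DEFAULT_INFO_KEYS
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
)

_SET_SEP = "|"   # multi-valued INFO fields (ClinVar terms, gene symbols)


class VcfParseError(ValueError):
    pass


def _decode_set(raw: Optional[str]) -> frozenset:
    if raw in (None, "", "."):
        return frozenset()
    return frozenset(t.replace("_", " ") for t in str(raw).split(_SET_SEP) if t)


def _encode_set(values) -> Optional[str]:
    if not values:
        return None
    return _SET_SEP.join(sorted(v.replace(" ", "_") for v in values))


def _per_allele(value, allele_index: int, n_alts: int):
    """Pick the value for one ALT from a possibly per-allele INFO field."""
    if value is None:
        return None
    if isinstance(value, tuple):
        if len(value) == n_alts:
            value = value[allele_index]
        else:
            value = value[0]
    if isinstance(value, str) and "," in value and n_alts > 1:
        parts = value.split(",")
        if len(parts) == n_alts:
            value = parts[allele_index]
    return value


def _zygosity_from_gt(gt: list, allele_index: int) -> Zygosity:
    # cyvcf2 genotype entry: [a1, a2, phased] diploid or [a1, phased] haploid
    alleles = gt[:-1]
    if any(a is None or a < 0 for a in alleles):
        return Zygosity.MISSING
    k = allele_index + 1
    hits = sum(1 for a in alleles if a == k)
    if len(alleles) == 1:
        return Zygosity.HEMI_ALT if hits else Zygosity.HOM_REF
    if hits == 0:
        return Zygosity.HOM_REF
    if hits == 1:
        return Zygosity.HET
    return Zygosity.HOM_ALT


def read_annotated_vcf(path, info_key_map: Optional[dict] = None
                       ) -> list[AnnotatedVariant]:
    """Read an annotated VCF into one :class:`AnnotatedVariant` per ALT.

    ``info_key_map`` maps annotation-bundle field names to the INFO keys of
    the annotator dialect in use (defaults: GNOMAD_AF, EXAC_AF, CADD_PHRED,
    SIFT, PP2_HVAR, MT, METASVM, GERP_RS, CLNSIG, GENE, CSQ_CLASS).
    Multi-allelic records are split per ALT before annotation lookup.
    """
    keys = dict(DEFAULT_INFO_KEYS)
    if info_key_map:
        keys.update(info_key_map)
    out: list[AnnotatedVariant] = []
    vcf = cyvcf2.VCF(str(path))
    samples = list(vcf.samples)
    try:
        for line_no, rec in enumerate(vcf, start=1):
            try:
                out.extend(_split_record(rec, samples, keys))
            except VcfParseError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate with location
                raise VcfParseError(
                    f"malformed VCF record #{line_no} at "
                    f"{rec.CHROM}:{rec.POS}: {exc}") from exc
    finally:
        vcf.close()
    return out


def _float_or_none(value) -> Optional[float]:
    # VCF floats are single precision; normalize to 6 significant digits
    if value is None or value in (".", ""):
        return None
    return float(f"{float(value):.6g}")


def _str_or_none(value) -> Optional[str]:
    if value is None or value in (".", ""):
        return None
    return str(value)


def _split_record(rec, samples, keys) -> list[AnnotatedVariant]:
    n_alts = len(rec.ALT)
    gts = rec.genotypes if samples else []
    variants = []
    for ai, alt in enumerate(rec.ALT):
        def info(field):
            return _per_allele(rec.INFO.get(keys[field]), ai, n_alts)

        ann = AnnotationBundle(
            gnomad_af=_float_or_none(info("gnomad_af")),
            exac_af=_float_or_none(info("exac_af")),
            cadd_phred=_float_or_none(info("cadd_phred")),
            sift=_str_or_none(info("sift")),
            polyphen2_hvar=_str_or_none(info("polyphen2_hvar")),
            mutation_taster=_str_or_none(info("mutation_taster")),
            metasvm=_str_or_none(info("metasvm")),
            gerp_rs=_float_or_none(info("gerp_rs")),
            clinvar_terms=_decode_set(rec.INFO.get(keys["clinvar_terms"])),
            gene_symbols=_decode_set(rec.INFO.get(keys["gene_symbols"])),
            consequence=_str_or_none(info("consequence")),
            heteroplasmy_fraction=_float_or_none(
                info("heteroplasmy_fraction")),
        )
        vclass = ("SNV" if len(rec.REF) == len(alt) == 1 else "indel")
        genos = [
            GenotypeCall(sample_id=s, zygosity=_zygosity_from_gt(gts[si], ai))
            for si, s in enumerate(samples)
        ]
        variants.append(AnnotatedVariant(
            contig=rec.CHROM, position=rec.POS, ref=rec.REF, alt=alt,
            variant_class=vclass, annotations=ann, genotypes=genos,
            pass_flag=rec.FILTER is None,
        ))
    return variants


_INFO_HEADER = [
    ("GNOMAD_AF", "1", "Float", "gnomAD allele frequency"),
    ("EXAC_AF", "1", "Float", "ExAC allele frequency"),
    ("CADD_PHRED", "1", "Float", "CADD scaled score"),
    ("SIFT", "1", "String", "SIFT call (D/T)"),
    ("PP2_HVAR", "1", "String", "PolyPhen2 HVAR call (D/P/B)"),
    ("MT", "1", "String", "MutationTaster call (A/D/N/P)"),
    ("METASVM", "1", "String", "MetaSVM call (D/T)"),
    ("GERP_RS", "1", "Float", "GERP++ RS score"),
    ("CLNSIG", "1", "String", "ClinVar significance terms"),
    ("GENE", "1", "String", "Gene symbols"),
    ("CSQ_CLASS", "1", "String", "Consequence class"),
    ("HET_FRAC", "1", "Float", "Mitochondrial heteroplasmy fraction"),
]

_GT_FOR = {
    Zygosity.HOM_REF: (0, 0),
    Zygosity.HET: (0, 1),
    Zygosity.HOM_ALT: (1, 1),
    Zygosity.HEMI_ALT: (1,),
    Zygosity.MISSING: (None, None),
}


def write_annotated_vcf(path, variants: list[AnnotatedVariant],
                        samples: Optional[list[str]] = None,
                        contig_lengths: Optional[dict] = None) -> None:
    """Write SNV/indel variants (one record per ALT) to a VCF."""
    if samples is None:
        seen: dict[str, None] = {}
        for v in variants:
            for g in v.genotypes:
                seen.setdefault(g.sample_id, None)
        samples = list(seen)
    header = pysam.VariantHeader()
    contigs = dict(contig_lengths or {})
    for v in variants:
        contigs.setdefault(v.contig, 500_000_000)
    for ctg, length in contigs.items():
        header.contigs.add(ctg, length=length)
    for name, num, typ, desc in _INFO_HEADER:
        header.info.add(name, num, typ, desc)
    header.formats.add("GT", 1, "String", "Genotype")
    for s in samples:
        header.add_sample(s)
    order = {c: i for i, c in enumerate(contigs)}
    variants = sorted(variants, key=lambda v: (order[v.contig], v.position,
                                               v.ref, v.alt))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.contig, start=v.position - 1,
                stop=v.position - 1 + len(v.ref),
                alleles=(v.ref, v.alt))
            rec.filter.add("PASS" if v.pass_flag else "FAIL")
            a = v.annotations
            for field, key in (
                    ("gnomad_af", "GNOMAD_AF"), ("exac_af", "EXAC_AF"),
                    ("cadd_phred", "CADD_PHRED"), ("sift", "SIFT"),
                    ("polyphen2_hvar", "PP2_HVAR"),
                    ("mutation_taster", "MT"), ("metasvm", "METASVM"),
                    ("gerp_rs", "GERP_RS"), ("consequence", "CSQ_CLASS"),
                    ("heteroplasmy_fraction", "HET_FRAC")):
                val = getattr(a, field)
                if val is not None:
                    rec.info[key] = val
            if a.clinvar_terms:
                rec.info["CLNSIG"] = _encode_set(a.clinvar_terms)
            if a.gene_symbols:
                rec.info["GENE"] = _encode_set(a.gene_symbols)
            by_sample = {g.sample_id: g.zygosity for g in v.genotypes}
            for s in samples:
                rec.samples[s]["GT"] = _GT_FOR[
                    by_sample.get(s, Zygosity.MISSING)]
            out.write(rec)


# ---------------------------------------------------------------- pedigree

def read_pedigree(path) -> PedigreeGraph:
    """Read a 6-column PED file and infer proband/parent/sibling roles.

    Children are rows with a parent pointer or rows nobody points to; the
    affected child of each family is the proband. Duos and singletons are
    allowed (absent parents coded ``0``).
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: expected 6 PED columns")
            rows.append(parts[:6])
    return pedigree_from_rows(rows)


def pedigree_from_rows(rows: list[list[str]]) -> PedigreeGraph:
    sex_map = {"1": "male", "2": "female"}
    parent_ids = set()
    mother_ids = set()
    father_ids = set()
    for fam, sid, fid, mid, sex, pheno in rows:
        if fid != "0":
            parent_ids.add(fid)
            father_ids.add(fid)
        if mid != "0":
            parent_ids.add(mid)
            mother_ids.add(mid)
    members = []
    for fam, sid, fid, mid, sex, pheno in rows:
        affected = pheno == "2"
        if sid in father_ids:
            role = "father"
        elif sid in mother_ids:
            role = "mother"
        elif affected:
            role = "proband"
        else:
            role = "sibling"
        members.append(PedigreeMember(
            sample_id=sid, family_id=fam,
            father_id=None if fid == "0" else fid,
            mother_id=None if mid == "0" else mid,
            sex=sex_map.get(sex, "unknown"), affected=affected, role=role))
    return PedigreeGraph(members)


def write_pedigree(path, pedigree: PedigreeGraph) -> None:
    sex_map = {"male": "1", "female": "2", "unknown": "0"}
    with open(path, "w") as fh:
        for m in pedigree.members:
            fh.write("\t".join([
                m.family_id, m.sample_id,
                m.father_id or "0", m.mother_id or "0",
                sex_map[m.sex], "2" if m.affected else "1"]) + "\n")


# --------------------------------------------------------------- CNV table

CNV_COLUMNS = ["sample", "contig", "start", "end", "type",
               "mgrb_af", "genes", "pass_flag"]


def read_cnv_table(path) -> list[AnnotatedVariant]:
    """Read a BED-like CNV call table (0-based half-open) into CNV variants.

    Coordinates convert to 1-based inclusive: position = start + 1,
    span_end = end. The carrier sample's genotype is recorded as het
    (hemi for male X handled downstream via pedigree sex).
    """
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for ln, row in enumerate(reader, start=2):
            start = int(row["start"])
            end = int(row["end"])
            if end <= start:
                raise ValueError(
                    f"{path}:{ln}: CNV end {end} <= start {start}")
            ctype = row["type"].upper()
            vclass = "CNV_DEL" if ctype == "DEL" else "CNV_DUP"
            vclass = {"CNV_DEL": "CNV_del", "CNV_DUP": "CNV_dup"}[vclass]
            genes = frozenset(g for g in row["genes"].split(",") if g)
            af = None if row["mgrb_af"] in ("", "NA", ".") \
                else float(row["mgrb_af"])
            ann = AnnotationBundle(mgrb_af=af, gene_symbols=genes,
                                   consequence="cnv")
            out.append(AnnotatedVariant(
                contig=row["contig"], position=start + 1, ref="N",
                alt="<DEL>" if vclass == "CNV_del" else "<DUP>",
                variant_class=vclass, span_end=end, annotations=ann,
                genotypes=[GenotypeCall(row["sample"], Zygosity.HET)],
                pass_flag=row["pass_flag"] in ("1", "True", "PASS", "true"),
            ))
    return out


def write_cnv_table(path, cnvs: list[AnnotatedVariant]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(CNV_COLUMNS)
        for v in cnvs:
            carrier = v.genotypes[0].sample_id if v.genotypes else ""
            w.writerow([
                carrier, v.contig, v.position - 1, v.span_end,
                "DEL" if v.variant_class == "CNV_del" else "DUP",
                "" if v.annotations.mgrb_af is None
                else repr(v.annotations.mgrb_af),
                ",".join(sorted(v.annotations.gene_symbols)),
                "1" if v.pass_flag else "0"])


# -------------------------------------------------------------- phenotypes

PHENOTYPE_COLUMNS = ["sample_id", "sex", "gestational_age_weeks",
                     "birth_weight_centile", "autism", "developmental_delay",
                     "epilepsy", "imaging_class", "batch_id"]


def _cell(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _parse_bool(raw: str) -> Optional[bool]:
    if raw in ("NA", "", "."):
        return None
    return raw in ("1", "True", "true")


def read_phenotype_table(path) -> list[SamplePhenotype]:
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(SamplePhenotype(
                sample_id=row["sample_id"],
                sex=None if row["sex"] == "NA" else row["sex"],
                gestational_age_weeks=_float_or_none(
                    row["gestational_age_weeks"].replace("NA", ".")),
                birth_weight_centile=_float_or_none(
                    row["birth_weight_centile"].replace("NA", ".")),
                autism=_parse_bool(row["autism"]),
                developmental_delay=_parse_bool(row["developmental_delay"]),
                epilepsy=_parse_bool(row["epilepsy"]),
                imaging_class=None if row["imaging_class"] == "NA"
                else row["imaging_class"],
                batch_id=None if row["batch_id"] == "NA" else row["batch_id"],
            ))
    return out


def write_phenotype_table(path, phenotypes: list[SamplePhenotype]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(PHENOTYPE_COLUMNS)
        for p in phenotypes:
            w.writerow([_cell(getattr(p, c)) for c in PHENOTYPE_COLUMNS])


# ----------------------------------------------------------- gene resource

GENE_RESOURCE_COLUMNS = ["gene", "panels", "missense_z", "lof_oe",
                         "inheritance_mode", "domino_label",
                         "penetrance_caveat", "lof_mechanism", "omim",
                         "aetiology"]


def read_gene_resource_table(path) -> GeneResourceTable:
    with open(path) as fh:
        return gene_resources_from_rows(csv.DictReader(fh, delimiter="\t"))


def gene_resources_from_rows(rows) -> GeneResourceTable:
    resources = []
    for row in rows:
        resources.append(GeneResource(
            gene=row["gene"],
            panels=frozenset(p for p in row["panels"].split(",") if p),
            missense_z=_float_or_none(row["missense_z"].replace("NA", ".")),
            lof_oe=_float_or_none(row["lof_oe"].replace("NA", ".")),
            inheritance_mode=row["inheritance_mode"] or "unknown",
            domino_label=None if row["domino_label"] in ("NA", "")
            else row["domino_label"],
            penetrance_caveat=row["penetrance_caveat"] == "1",
            lof_mechanism=row["lof_mechanism"] == "1",
            omim=row["omim"] == "1",
            aetiology=None if row["aetiology"] in ("NA", "")
            else row["aetiology"],
        ))
    return GeneResourceTable(resources)


def write_gene_resource_table(path, table: GeneResourceTable) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(GENE_RESOURCE_COLUMNS)
        for gene in table.genes():
            r = table.get(gene)
            w.writerow([
                r.gene, ",".join(sorted(r.panels)),
                _cell(r.missense_z), _cell(r.lof_oe), r.inheritance_mode,
                _cell(r.domino_label), _cell(r.penetrance_caveat),
                _cell(r.lof_mechanism), _cell(r.omim), _cell(r.aetiology)])


# -------------------------------------------------- curated ACMG evidence

class CuratedEvidence:
    """Curated per-variant ACMG assertions and clinical flags.

    Rows carry an ACMG tag (with provenance "curated") or one of the flag
    pseudo-tags ``risk_allele`` / ``phenotype_fit``.
    """

    def __init__(self):
        self.tags: dict[str, set[str]] = {}
        self.risk_alleles: set[str] = set()
        # variant key -> phenotype-fit level: full | partial | none
        self.phenotype_fit: dict[str, str] = {}

    def add(self, variant_key: str, tag: str) -> None:
        if tag == "risk_allele":
            self.risk_alleles.add(variant_key)
        elif tag in ("phenotype_fit", "phenotype_fit_full"):
            self.phenotype_fit[variant_key] = "full"
        elif tag == "phenotype_fit_partial":
            self.phenotype_fit[variant_key] = "partial"
        elif tag == "phenotype_fit_none":
            self.phenotype_fit[variant_key] = "none"
        else:
            self.tags.setdefault(variant_key, set()).add(tag)

    def tags_for(self, variant_key: str) -> set[str]:
        return set(self.tags.get(variant_key, set()))

    def fit_for(self, variant_key: str) -> str:
        return self.phenotype_fit.get(variant_key, "unknown")


def read_curated_evidence(path) -> CuratedEvidence:
    ev = CuratedEvidence()
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            ev.add(row["variant_key"], row["tag"])
    return ev


def write_curated_evidence(path, ev: CuratedEvidence) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["variant_key", "tag", "provenance"])
        for key in sorted(ev.tags):
            for tag in sorted(ev.tags[key]):
                w.writerow([key, tag, "curated"])
        for key in sorted(ev.risk_alleles):
            w.writerow([key, "risk_allele", "curated"])
        for key in sorted(ev.phenotype_fit):
            w.writerow([key, f"phenotype_fit_{ev.phenotype_fit[key]}",
                        "curated"])


# ------------------------------------------------------- external phasing

def read_external_phase(path) -> dict[frozenset, str]:
    """Long-read phasing results: {frozenset({key_a, key_b}): phase}."""
    out = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out[frozenset((row["variant_a"], row["variant_b"]))] = row["phase"]
    return out


def write_external_phase(path, phases: dict[frozenset, str]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["variant_a", "variant_b", "phase"])
        for pair, phase in sorted(phases.items(), key=lambda kv: sorted(kv[0])):
            a, b = sorted(pair)
            w.writerow([a, b, phase])


# --------------------------------------------------------- gene model TSV

def read_gene_model(path) -> list[dict]:
    """Toy gene model: gene, contig, coding start/end (1-based inclusive)."""
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append({"gene": row["gene"], "contig": row["contig"],
                        "coding_start": int(row["coding_start"]),
                        "coding_end": int(row["coding_end"])})
    return out
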