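"""Shared fixtures: tiny pedigrees, variant builders, a small synthetic cohort."""

from __future__ import annotations

import pytest

from cpvar.simulate import SimConfig, generate_cohort
from cpvar.types import (
    AnnotatedVariant,
    AnnotationBundle,
    GenotypeCall,
    PedigreeGraph,
    PedigreeMember,
    Zygosity,
)


def make_variant(contig="1", pos=1000, ref="A", alt="G", vclass="SNV",
                 genotypes=(), **ann):
    return AnnotatedVariant(
        contig=contig, position=pos, ref=ref, alt=alt, variant_class=vclass,
        annotations=AnnotationBundle(**ann),
        genotypes=[GenotypeCall(s, Zygosity(z)) for s, z in genotypes])


def trio_pedigree(proband="P1", mother="M1", father="F1",
                  siblings=(), family="FAM1"):
    members = [
        PedigreeMember(proband, family, father, mother, "male", True,
                       "proband"),
        PedigreeMember(mother, family, None, None, "female", False,
                       "mother"),
        PedigreeMember(father, family, None, None, "male", False, "father"),
    ]
    for s in siblings:
        members.append(PedigreeMember(s, family, father, mother, "female",
                                      False, "sibling"))
    return PedigreeGraph(members)


def duo_pedigree(proband="P1", parent="M1", parent_role="mother",
                 family="FAM1"):
    mother_id = parent if parent_role == "mother" else None
    father_id = parent if parent_role == "father" else None
    sex = "female" if parent_role == "mother" else "male"
    return PedigreeGraph([
        PedigreeMember(proband, family, father_id, mother_id, "male", True,
                       "proband"),
        PedigreeMember(parent, family, None, None, sex, False, parent_role),
    ])


def singleton_pedigree(proband="P1", family="FAM1"):
    return PedigreeGraph([
        PedigreeMember(proband, family, None, None, "male", True,
                       "proband"),
    ])


SMALL_SIM = SimConfig(
    n_probands=40, n_trios=6, n_duos_maternal=8, n_duos_paternal=2,
    n_singletons=24, n_male=24, n_diagnosed=12, n_cnv_diagnosed=2,
    n_risk_factor=3, n_trio_diagnosed=3, n_comorbidity_missing=3,
    batch_size=20, background_variants_per_proband=5)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 40-proband synthetic cohort with 12 planted diagnoses."""
    outdir = tmp_path_factory.mktemp("small_cohort")
    truth = generate_cohort(SMALL_SIM, seed=11, outdir=outdir)
    return outdir, truth


@pytest.fixture(scope="session")
def default_cohort(tmp_path_factory):
    """The full study-condition cohort (150 probands, 37 planted)."""
    outdir = tmp_path_factory.mktemp("default_cohort")
    truth = generate_cohort(SimConfig(), seed=2024, outdir=outdir)
    return outdir, truth


def cohort_inputs(directory) -> dict:
    from pathlib import Path
    d = Path(directory)
    return {
        "vcf": str(d / "cohort.vcf"), "ped": str(d / "cohort.ped"),
        "cnv": str(d / "cnv_calls.tsv"),
        "phenotypes": str(d / "phenotypes.tsv"),
        "gene_resources": str(d / "gene_resources.tsv"),
        "curated_evidence": str(d / "curated_evidence.tsv"),
    }
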