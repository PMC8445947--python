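"""SNV filter tracks: boundaries, brute-force oracles, union semantics."""

import warnings

import numpy as np
import pytest

from conftest import duo_pedigree, make_variant, singleton_pedigree, \
    trio_pedigree
from cpvar.config import FilterConfig
from cpvar.snv_filters import (
    BatchConfigurationError,
    FilterVerdict,
    batch_allele_filter,
    clinvar_is_pathogenic,
    filter1_rare_deleterious,
    filter3_known_pathogenic,
    insilico_vote,
    intolerant_gene_vus,
    prioritize_proband,
    second_hit_search,
)
from cpvar.types import GeneResource, GeneResourceTable

CFG = FilterConfig()
PANEL_GENE = GeneResourceTable([
    GeneResource("PANELG", panels=frozenset({"CP"}), omim=True),
    GeneResource("PLAING"),
])

DELETERIOUS = dict(sift="D", polyphen2_hvar="D", mutation_taster="A",
                   metasvm="D", gerp_rs=5.0)
BENIGN = dict(sift="T", polyphen2_hvar="B", mutation_taster="N",
              metasvm="T", gerp_rs=-2.0)


# ------------------------------------------------------------ batch filter

def _batch_variant(n_carriers, batch="B1"):
    genos = [(f"S{i}", "het") for i in range(n_carriers)]
    return make_variant(genotypes=genos), \
        {f"S{i}": batch for i in range(60)}


@pytest.mark.parametrize("ac,survives", [(1, True), (2, True), (3, False)])
def test_batch_allele_count_boundary(ac, survives):
    v, batch_map = _batch_variant(ac)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = batch_allele_filter([v], batch_map)
    assert bool(out) == survives


def test_batch_filter_counts_hom_as_two_alleles():
    v = make_variant(genotypes=[("S0", "hom_alt"), ("S1", "het")])
    batch_map = {f"S{i}": "B1" for i in range(60)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        assert batch_allele_filter([v], batch_map) == []


def test_batch_filter_matches_brute_force_recount():
    rng = np.random.default_rng(5)
    samples = [f"S{i}" for i in range(120)]
    batch_map = {s: f"B{i % 3}" for i, s in enumerate(samples)}
    variants = []
    for _ in range(200):
        k = int(rng.integers(1, 6))
        carriers = rng.choice(samples, size=k, replace=False)
        variants.append(make_variant(
            genotypes=[(str(c), "het") for c in carriers]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        survivors = batch_allele_filter(variants, batch_map)
    expected = []
    for v in variants:
        per_batch = {}
        for g in v.genotypes:
            per_batch[batch_map[g.sample_id]] = \
                per_batch.get(batch_map[g.sample_id], 0) + 1
        if max(per_batch.values()) <= 2:
            expected.append(v)
    assert survivors == expected


def test_carrier_without_batch_is_configuration_error():
    v = make_variant(genotypes=[("GHOST", "het")])
    with pytest.raises(BatchConfigurationError):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            batch_allele_filter([v], {"OTHER": "B1"})


def test_small_batch_warns():
    v, _ = _batch_variant(1)
    with pytest.warns(UserWarning, match="samples"):
        batch_allele_filter([v], {f"S{i}": "B1" for i in range(5)})


# ----------------------------------------------------------- in-silico vote

def test_insilico_vote_all_deleterious_and_all_benign():
    v = make_variant(**DELETERIOUS)
    assert insilico_vote(v.annotations) == (5, 5)
    v = make_variant(**BENIGN)
    assert insilico_vote(v.annotations) == (0, 5)


def test_insilico_vote_matches_independent_recount():
    rng = np.random.default_rng(9)
    sift_v = ["D", "T", None]
    pp2_v = ["D", "P", "B", None]
    mt_v = ["A", "D", "N", "P", None]
    svm_v = ["D", "T", None]
    for _ in range(300):
        ann = dict(
            sift=sift_v[rng.integers(3)],
            polyphen2_hvar=pp2_v[rng.integers(4)],
            mutation_taster=mt_v[rng.integers(5)],
            metasvm=svm_v[rng.integers(3)],
            gerp_rs=None if rng.random() < 0.2
            else float(rng.uniform(-5, 8)))
        votes, avail = insilico_vote(make_variant(**ann).annotations)
        exp_votes = sum([
            ann["sift"] == "D",
            ann["polyphen2_hvar"] in ("D", "P"),
            ann["mutation_taster"] in ("A", "D"),
            ann["metasvm"] == "D",
            ann["gerp_rs"] is not None and ann["gerp_rs"] > 4,
        ])
        exp_avail = sum(v is not None for v in ann.values())
        assert (votes, avail) == (exp_votes, exp_avail)


# ------------------------------------------------------------- filter 1

def _run_f1(v, resources=PANEL_GENE, cfg=CFG):
    verdict = FilterVerdict(v, "P1")
    return filter1_rare_deleterious(v, resources, cfg, verdict)


def test_filter1_rare_deleterious_panel_gene_passes():
    """Novel missense, CADD 29.8, panel gene: the published exemplar shape."""
    v = make_variant(gnomad_af=0.0, cadd_phred=29.8,
                     consequence="nonsynonymous",
                     gene_symbols={"PANELG"}, **DELETERIOUS)
    assert _run_f1(v)


def test_filter1_rejects_synonymous_regardless_of_scores():
    v = make_variant(gnomad_af=0.0, cadd_phred=25.0,
                     consequence="synonymous", gene_symbols={"PANELG"},
                     **DELETERIOUS)
    assert not _run_f1(v)


def test_filter1_missing_cadd_does_not_veto():
    v = make_variant(gnomad_af=0.0, cadd_phred=None,
                     consequence="frameshift", gene_symbols={"PANELG"})
    assert _run_f1(v)


def test_filter1_evidence_mode_all_requires_both_routes():
    cfg = FilterConfig(evidence_mode="all")
    votes_only = make_variant(gnomad_af=0.0, cadd_phred=25.0,
                              consequence="nonsynonymous",
                              gene_symbols={"PLAING"}, **DELETERIOUS)
    both = make_variant(gnomad_af=0.0, cadd_phred=25.0,
                        consequence="nonsynonymous",
                        gene_symbols={"PANELG"}, **DELETERIOUS)
    assert _run_f1(votes_only)                    # OR mode default
    assert not _run_f1(votes_only, cfg=cfg)       # AND mode needs panel too
    assert _run_f1(both, cfg=cfg)


def _random_f1_variants(n, rng):
    out = []
    freqs = [0.0, 5e-5, 9e-5, 1.1e-4, 1e-3, 0.02]
    csqs = ["nonsynonymous", "stopgain", "frameshift", "splicing",
            "synonymous", "noncoding"]
    for _ in range(n):
        ins = DELETERIOUS if rng.random() < 0.5 else BENIGN
        out.append(make_variant(
            gnomad_af=freqs[rng.integers(len(freqs))],
            exac_af=None if rng.random() < 0.5
            else freqs[rng.integers(len(freqs))],
            cadd_phred=None if rng.random() < 0.15
            else float(rng.uniform(5, 40)),
            consequence=csqs[rng.integers(len(csqs))],
            gene_symbols={"PANELG" if rng.random() < 0.4 else "PLAING"},
            **ins))
    return out


def test_filter1_matches_brute_force_predicate():
    rng = np.random.default_rng(17)
    for v in _random_f1_variants(1000, rng):
        a = v.annotations
        freqs = [f for f in (a.gnomad_af, a.exac_af) if f is not None]
        freq = max(freqs) if freqs else 0.0
        votes = sum([a.sift == "D", a.polyphen2_hvar in ("D", "P"),
                     a.mutation_taster in ("A", "D"), a.metasvm == "D",
                     a.gerp_rs is not None and a.gerp_rs > 4])
        expected = (
            a.consequence in ("nonsynonymous", "stopgain", "stoploss",
                              "frameshift", "nonframeshift_indel",
                              "splicing")
            and freq < 1e-4
            and (a.cadd_phred is None or a.cadd_phred > 20)
            and (votes >= 3 or "PANELG" in a.gene_symbols))
        assert _run_f1(v) == expected


def test_filter1_monotone_in_thresholds():
    """Tightening frequency or CADD thresholds never adds a pass."""
    rng = np.random.default_rng(23)
    variants = _random_f1_variants(300, rng)
    base = {v.key for v in variants if _run_f1(v)}
    tight_af = {v.key for v in variants
                if _run_f1(v, cfg=FilterConfig(filter1_af=5e-5))}
    tight_cadd = {v.key for v in variants
                  if _run_f1(v, cfg=FilterConfig(cadd_min=25.0))}
    assert tight_af <= base
    assert tight_cadd <= base


# ------------------------------------------------------------- filter 2

AR_RES = GeneResourceTable([
    GeneResource("ARG", panels=frozenset({"CP"}), inheritance_mode="AR"),
])


def _prioritize(pid, variants, ped, res=AR_RES, cfg=CFG, **kw):
    return prioritize_proband(pid, variants, ped, res, cfg, **kw)


def test_filter2_unknown_phase_pair_is_candidate():
    """Two het variants, no parents: kept as possible compound het."""
    ped = singleton_pedigree()
    va = make_variant(pos=100, genotypes=[("P1", "het")],
                      gnomad_af=2.06e-3, consequence="nonsynonymous",
                      gene_symbols={"ARG"})
    vb = make_variant(pos=200, genotypes=[("P1", "het")],
                      gnomad_af=1.43e-3, consequence="nonsynonymous",
                      gene_symbols={"ARG"})
    verdicts = _prioritize("P1", [va, vb], ped)
    assert "filter2" in verdicts[va.key].tracks_passed
    assert "filter2" in verdicts[vb.key].tracks_passed
    assert verdicts[va.key].recessive_partner.phase == "unknown"


def test_filter2_homozygote_below_one_percent_is_candidate():
    ped = singleton_pedigree()
    v = make_variant(genotypes=[("P1", "hom_alt")], gnomad_af=7.17e-3,
                     consequence="nonframeshift_indel", gene_symbols={"ARG"})
    verdicts = _prioritize("P1", [v], ped)
    assert "filter2" in verdicts[v.key].tracks_passed


def test_filter2_single_het_not_candidate():
    ped = singleton_pedigree()
    v = make_variant(genotypes=[("P1", "het")], gnomad_af=1e-3,
                     consequence="nonsynonymous", gene_symbols={"ARG"})
    verdicts = _prioritize("P1", [v], ped)
    assert "filter2" not in verdicts[v.key].tracks_passed


def test_filter2_cis_pair_rejected():
    ped = trio_pedigree()
    va = make_variant(pos=100, genotypes=[("P1", "het"), ("M1", "het"),
                                          ("F1", "hom_ref")],
                      gnomad_af=0.0, consequence="nonsynonymous",
                      gene_symbols={"ARG"})
    vb = make_variant(pos=200, genotypes=[("P1", "het"), ("M1", "het"),
                                          ("F1", "hom_ref")],
                      gnomad_af=0.0, consequence="nonsynonymous",
                      gene_symbols={"ARG"})
    verdicts = _prioritize("P1", [va, vb], ped)
    assert "filter2" not in verdicts[va.key].tracks_passed
    assert verdicts[va.key].recessive_partner.phase == "cis"


def test_filter2_digenic_requires_pair_list():
    ped = singleton_pedigree()
    va = make_variant(pos=100, genotypes=[("P1", "het")], gnomad_af=0.0,
                      consequence="nonsynonymous", gene_symbols={"GA"})
    vb = make_variant(pos=200, genotypes=[("P1", "het")], gnomad_af=0.0,
                      consequence="nonsynonymous", gene_symbols={"GB"})
    res = GeneResourceTable([GeneResource("GA"), GeneResource("GB")])
    off = _prioritize("P1", [va, vb], ped, res=res)
    assert "filter2" not in off[va.key].tracks_passed
    cfg = FilterConfig(digenic_pairs=(("GA", "GB"),))
    on = _prioritize("P1", [va, vb], ped, res=res, cfg=cfg)
    assert "filter2" in on[va.key].tracks_passed
    assert "filter2" in on[vb.key].tracks_passed


# ------------------------------------------------------------- filter 3

def test_clinvar_terms_pass_and_fail():
    assert clinvar_is_pathogenic({"Pathogenic"})
    assert clinvar_is_pathogenic({"Likely pathogenic"})
    assert clinvar_is_pathogenic({"Pathogenic/Likely pathogenic"})
    assert not clinvar_is_pathogenic({"Benign", "drug response"})
    assert not clinvar_is_pathogenic(
        {"Conflicting interpretations of pathogenicity"})
    assert not clinvar_is_pathogenic({"Likely benign"})


def test_filter3_noncoding_variant_passes_on_clinvar_term():
    """A 3'UTR risk allele with a P/LP assertion passes track 3 despite
    its non-coding consequence."""
    v = make_variant(gnomad_af=8.44e-3, consequence="noncoding",
                     gene_symbols={"F2"},
                     clinvar_terms={"Likely pathogenic"})
    verdict = FilterVerdict(v, "P1")
    assert filter3_known_pathogenic(v, verdict)
    assert verdict.clinvar_match == {"Likely pathogenic"}


def test_second_hit_search_finds_other_variants_in_ar_gene():
    first = make_variant(pos=100, genotypes=[("P1", "het")],
                         gnomad_af=3.24e-5, cadd_phred=29.4,
                         consequence="nonsynonymous", gene_symbols={"ARG"},
                         clinvar_terms={"Pathogenic"})
    second = make_variant(pos=200, genotypes=[("P1", "het")],
                          gnomad_af=2.5e-3, cadd_phred=23.0,
                          consequence="nonsynonymous", gene_symbols={"ARG"})
    hits = second_hit_search("P1", "ARG", [first, second], [], AR_RES,
                             exclude_keys={first.key})
    assert hits == [second]


def test_second_hit_search_empty_without_ar_mode_or_partner():
    v = make_variant(genotypes=[("P1", "het")], gene_symbols={"PANELG"})
    assert second_hit_search("P1", "PANELG", [v], [], PANEL_GENE) == []
    lone = make_variant(genotypes=[("P1", "het")], gene_symbols={"ARG"},
                        clinvar_terms={"Pathogenic"})
    assert second_hit_search("P1", "ARG", [lone], [], AR_RES,
                             exclude_keys={lone.key}) == []


def test_second_hit_search_includes_overlapping_cnv():
    snv = make_variant(pos=100, genotypes=[("P1", "het")],
                       gene_symbols={"ARG"}, clinvar_terms={"Pathogenic"})
    cnv = make_variant(pos=50, ref="N", alt="<DEL>", vclass="CNV_del",
                       genotypes=[("P1", "het")], gene_symbols={"ARG"},
                       mgrb_af=0.0, consequence="cnv")
    cnv.span_end = 500
    hits = second_hit_search("P1", "ARG", [snv], [cnv], AR_RES,
                             exclude_keys={snv.key})
    assert hits == [cnv]


# --------------------------------------------------------- intolerant VUS

INTOL = GeneResourceTable([
    GeneResource("ZGENE", missense_z=2.5, lof_oe=0.8),
    GeneResource("OEGENE", missense_z=0.5, lof_oe=0.4),
])


def test_intolerant_vus_rule_and_diagnosed_exclusion():
    v = make_variant(gnomad_af=0.0, cadd_phred=25.0,
                     consequence="nonsynonymous", gene_symbols={"ZGENE"})
    assert intolerant_gene_vus(v, INTOL, False, CFG)
    assert not intolerant_gene_vus(v, INTOL, True, CFG)


def test_intolerant_vus_matches_brute_force_predicate():
    rng = np.random.default_rng(31)
    genes = ["ZGENE", "OEGENE", "NOVEL"]
    csqs = ["nonsynonymous", "stopgain", "frameshift", "splicing",
            "synonymous"]
    for _ in range(500):
        g = genes[rng.integers(3)]
        csq = csqs[rng.integers(5)]
        v = make_variant(
            gnomad_af=[0.0, 9e-5, 2e-4][rng.integers(3)],
            cadd_phred=None if rng.random() < 0.1
            else float(rng.uniform(10, 35)),
            consequence=csq, gene_symbols={g})
        a = v.annotations
        lof = csq in ("stopgain", "frameshift", "splicing")
        expected = (
            a.population_frequency < 1e-4
            and a.cadd_phred is not None and a.cadd_phred > 20
            and ((csq == "nonsynonymous" and g == "ZGENE")
                 or (lof and g == "OEGENE")))
        assert intolerant_gene_vus(v, INTOL, False, CFG) == expected


# --------------------------------------------------------- union semantics

def test_track_union_matches_brute_force_on_synthetic_cohort(small_cohort):
    """The prioritized set equals the union of per-track pass sets,
    recomputed independently, for every proband of a synthetic cohort."""
    from cpvar.io import read_annotated_vcf, read_pedigree, \
        read_phenotype_table, read_gene_resource_table
    outdir, _ = small_cohort
    variants = read_annotated_vcf(outdir / "cohort.vcf")
    ped = read_pedigree(outdir / "cohort.ped")
    phenos = read_phenotype_table(outdir / "phenotypes.tsv")
    res = read_gene_resource_table(outdir / "gene_resources.tsv")
    batch_map = {p.sample_id: p.batch_id for p in phenos}
    for m in ped.members:
        batch_map.setdefault(m.sample_id, "parental")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        surviving = batch_allele_filter(variants, batch_map)
    for p in ped.probands[:10]:
        verdicts = prioritize_proband(p.sample_id, surviving, ped, res)
        union = {k for k, vd in verdicts.items() if vd.tracks_passed}
        per_track = set()
        for track in ("filter1", "filter2", "filter3"):
            per_track |= {k for k, vd in verdicts.items()
                          if track in vd.tracks_passed}
        assert union == per_track
        # filter1 verdict is independent of filter3 inputs: recompute alone
        for k, vd in verdicts.items():
            solo = FilterVerdict(vd.variant, p.sample_id)
            assert filter1_rare_deleterious(vd.variant, res, CFG, solo) == \
                ("filter1" in vd.tracks_passed)
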