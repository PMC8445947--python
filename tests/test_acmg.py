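"""ACMG engine: combining rules, dual-route equivalence, downgrade policy."""

import itertools

import numpy as np
import pytest

from conftest import make_variant, trio_pedigree
from cpvar.acmg import (
    ACMGEvidence,
    CLASS_ORDER,
    ClassifiedFinding,
    ContradictoryEvidenceError,
    apply_penetrance_downgrade,
    assign_aetiology,
    assign_clinical_significance,
    combine_acmg,
    derive_acmg_evidence,
)
from cpvar.config import FilterConfig
from cpvar.inheritance import InheritanceLabel
from cpvar.snv_filters import FilterVerdict
from cpvar.types import GeneResource, GeneResourceTable


# ------------------------------------------------- independent rule oracle

def _tally(tags):
    return (int("PVS1" in tags),
            len([t for t in tags if t[:2] == "PS"]),
            len([t for t in tags if t[:2] == "PM"]),
            len([t for t in tags if t[:2] == "PP"]),
            int("BA1" in tags),
            len([t for t in tags if t[:2] == "BS"]),
            len([t for t in tags if t[:2] == "BP"]))


# the published combining rules as data: (min pvs, min ps, min pm, min pp)
_PATHOGENIC_RULES = [
    (1, 1, 0, 0), (1, 0, 2, 0), (1, 0, 1, 1), (1, 0, 0, 2),
    (0, 2, 0, 0),
    (0, 1, 3, 0), (0, 1, 2, 2), (0, 1, 1, 4),
]
_LIKELY_RULES = [
    (1, 0, 1, 0),
    (0, 1, 1, 0),
    (0, 1, 0, 2),
    (0, 0, 3, 0), (0, 0, 2, 2), (0, 0, 1, 4),
]


def oracle_combine(tags):
    """Second, independently coded decision procedure over the rule data."""
    pvs, ps, pm, pp, ba, bs, bp = _tally(tags)

    def meets(rule):
        need_pvs, need_ps, need_pm, need_pp = rule
        return (pvs >= need_pvs and ps >= need_ps and pm >= need_pm
                and pp >= need_pp)

    pathogenic_side = None
    if any(meets(r) for r in _PATHOGENIC_RULES):
        pathogenic_side = "pathogenic"
    elif any(meets(r) for r in _LIKELY_RULES):
        pathogenic_side = "likely_pathogenic"

    benign_side = None
    if ba >= 1 or bs >= 2:
        benign_side = "benign"
    elif (bs >= 1 and bp >= 1) or bp >= 2:
        benign_side = "likely_benign"

    if pathogenic_side and benign_side:
        return "uncertain"
    return pathogenic_side or benign_side or "uncertain"


UNIVERSE = ["PVS1", "PS1", "PS2", "PS3", "PM1", "PM2", "PM3", "PM4",
            "PP1", "PP2", "PP3", "PP4", "BA1", "BS1", "BS2", "BP1"]


def test_dual_implementation_equivalence_over_full_lattice():
    """All 2^16 subsets of a 16-tag universe classify identically under
    the rule table and the independent rule-data oracle."""
    for mask in range(1 << 16):
        tags = {UNIVERSE[i] for i in range(16) if mask >> i & 1}
        assert combine_acmg(tags) == oracle_combine(tags), sorted(tags)


@pytest.mark.parametrize("tags,expected", [
    ({"PVS1", "PM2"}, "likely_pathogenic"),
    ({"PVS1", "PS3"}, "pathogenic"),
    ({"PVS1", "PM1", "PM2"}, "pathogenic"),
    ({"PS1", "PS3"}, "pathogenic"),
    ({"PS3", "PM2"}, "likely_pathogenic"),
    ({"PS3", "PP1", "PP3"}, "likely_pathogenic"),
    ({"PM1", "PM2", "PM3"}, "likely_pathogenic"),
    ({"PS3", "PM1", "PM2", "PM4"}, "pathogenic"),
    (set(), "uncertain"),
    ({"PP3"}, "uncertain"),
    ({"BA1"}, "benign"),
    ({"BS1", "BS2"}, "benign"),
    ({"BS1", "BP1"}, "likely_benign"),
    ({"BP1", "BP4"}, "likely_benign"),
    ({"PS1", "PS2", "BA1"}, "uncertain"),     # conflicting evidence
])
def test_combine_published_rule_statements(tags, expected):
    assert combine_acmg(tags) == expected


# --------------------------------------------------------- auto evidence

GENES = GeneResourceTable([
    GeneResource("LOFG", lof_oe=0.2, lof_mechanism=True,
                 inheritance_mode="AD"),
    GeneResource("TOLG", lof_oe=0.9, inheritance_mode="AD"),
    GeneResource("CAVG", inheritance_mode="AD", penetrance_caveat=True),
    GeneResource("ARG", inheritance_mode="AR"),
    GeneResource("SPAST", aetiology="HSP"),
    GeneResource("COL4A1", aetiology="stroke_cardiovascular"),
    GeneResource("NDDG", aetiology="NDD"),
])
CFG = FilterConfig()


def _verdict_with_votes(v, n):
    verdict = FilterVerdict(v, "P1")
    verdict.insilico_votes = n
    verdict.insilico_available = 5
    return verdict


def test_de_novo_fitting_missense_gets_expected_auto_tags():
    v = make_variant(gnomad_af=0.0, consequence="nonsynonymous",
                     gene_symbols={"TOLG"})
    ev = derive_acmg_evidence(v, _verdict_with_votes(v, 5),
                              InheritanceLabel("de_novo"), GENES,
                              phenotype_fit="full")
    assert ev.tags == {"PS2", "PM2", "PP3", "PP4"}
    assert all(ev.provenance[t] == "auto" for t in ev.tags)


def test_lof_in_intolerant_gene_gets_pvs1():
    v = make_variant(gnomad_af=0.0, consequence="stopgain",
                     gene_symbols={"LOFG"})
    ev = derive_acmg_evidence(v, None, InheritanceLabel("unknown"), GENES)
    assert "PVS1" in ev.tags
    v2 = make_variant(gnomad_af=0.0, consequence="stopgain",
                      gene_symbols={"TOLG"})
    ev2 = derive_acmg_evidence(v2, None, InheritanceLabel("unknown"), GENES)
    assert "PVS1" not in ev2.tags


def test_common_variant_gets_ba1():
    v = make_variant(gnomad_af=0.06, consequence="nonsynonymous",
                     gene_symbols={"TOLG"})
    ev = derive_acmg_evidence(v, None, InheritanceLabel("unknown"), GENES)
    assert ev.tags == {"BA1"}


def test_contradictory_curated_pm2_with_auto_ba1_raises():
    v = make_variant(gnomad_af=0.06, consequence="nonsynonymous",
                     gene_symbols={"TOLG"})
    with pytest.raises(ContradictoryEvidenceError):
        derive_acmg_evidence(v, None, InheritanceLabel("unknown"), GENES,
                             curated_tags={"PM2"})


def test_auto_tags_match_independent_predicate_table():
    rng = np.random.default_rng(12)
    genes = ["LOFG", "TOLG"]
    csqs = ["nonsynonymous", "stopgain", "frameshift"]
    labels = ["de_novo", "maternal", "unknown"]
    fits = ["full", "unknown"]
    for _ in range(300):
        g = genes[rng.integers(2)]
        csq = csqs[rng.integers(3)]
        freq = [0.0, 5e-5, 2e-2, 0.06][rng.integers(4)]
        votes = int(rng.integers(0, 6))
        label = labels[rng.integers(3)]
        fit = fits[rng.integers(2)]
        v = make_variant(gnomad_af=freq, consequence=csq,
                         gene_symbols={g})
        ev = derive_acmg_evidence(v, _verdict_with_votes(v, votes),
                                  InheritanceLabel(label), GENES,
                                  phenotype_fit=fit)
        expected = set()
        if csq in ("stopgain", "frameshift") and g == "LOFG":
            expected.add("PVS1")
        if freq < 1e-4:
            expected.add("PM2")
        if freq > 0.05:
            expected.add("BA1")
        elif freq > 0.01:
            expected.add("BS1")
        if votes >= 3:
            expected.add("PP3")
        if label == "de_novo":
            expected.add("PS2")
        if fit == "full":
            expected.add("PP4")
        assert ev.tags == expected


# ----------------------------------------------------------- downgrade

def _finding(genes=("TOLG",), acmg="likely_pathogenic"):
    return ClassifiedFinding(variant_keys=("k",), case_id="P1",
                             genes=tuple(genes), acmg_class=acmg)


def test_inherited_lp_without_caveat_downgraded_to_uncertain():
    f = apply_penetrance_downgrade(_finding(), InheritanceLabel("maternal"),
                                   parent_affected=False,
                                   gene_resource=GENES)
    assert f.acmg_class == "uncertain"
    assert f.downgrade_applied


def test_penetrance_caveat_retains_class():
    f = apply_penetrance_downgrade(_finding(genes=("CAVG",)),
                                   InheritanceLabel("maternal"),
                                   parent_affected=False,
                                   gene_resource=GENES)
    assert f.acmg_class == "likely_pathogenic"
    assert not f.downgrade_applied


def test_de_novo_and_affected_parent_unchanged():
    f = apply_penetrance_downgrade(_finding(), InheritanceLabel("de_novo"),
                                   False, GENES)
    assert f.acmg_class == "likely_pathogenic"
    f = apply_penetrance_downgrade(_finding(), InheritanceLabel("maternal"),
                                   True, GENES)
    assert f.acmg_class == "likely_pathogenic"


def test_recessive_gene_exempt_from_downgrade():
    f = apply_penetrance_downgrade(_finding(genes=("ARG",), acmg="pathogenic"),
                                   InheritanceLabel("paternal"), False, GENES)
    assert f.acmg_class == "pathogenic"


def test_downgrade_never_upgrades():
    """After the downgrade step the class is <= the input class."""
    rng = np.random.default_rng(4)
    classes = list(CLASS_ORDER)
    labels = ["de_novo", "maternal", "paternal", "unknown", "biparental"]
    for _ in range(200):
        cls = classes[rng.integers(len(classes))]
        genes = ("CAVG",) if rng.random() < 0.5 else ("TOLG",)
        f = apply_penetrance_downgrade(
            _finding(genes=genes, acmg=cls),
            InheritanceLabel(labels[rng.integers(len(labels))]),
            bool(rng.random() < 0.5), GENES)
        assert CLASS_ORDER[f.acmg_class] <= CLASS_ORDER[cls]


# --------------------------------------------- significance and aetiology

@pytest.mark.parametrize("acmg,fit,risk,expected", [
    ("pathogenic", "full", False, "causative"),
    ("likely_pathogenic", "full", False, "causative"),
    ("likely_pathogenic", "partial", False, "risk_factor"),
    ("uncertain", "unknown", True, "risk_factor"),    # curated risk allele
    ("pathogenic", "none", False, "incidental"),
    ("pathogenic", "unknown", False, "uncertain"),
    ("uncertain", "full", False, "uncertain"),
])
def test_clinical_significance_mapping(acmg, fit, risk, expected):
    f = assign_clinical_significance(_finding(acmg=acmg), fit, risk)
    assert f.clinical_significance == expected
    assert f.trace


def test_aetiology_from_gene_sets():
    assert assign_aetiology(_finding(genes=("SPAST",)), GENES).aetiology \
        == "HSP"
    assert assign_aetiology(_finding(genes=("COL4A1",)), GENES).aetiology \
        == "stroke_cardiovascular"
    assert assign_aetiology(_finding(genes=("TOLG",)), GENES).aetiology \
        is None


def test_gene_in_two_aetiology_groups_is_error():
    with pytest.raises(ValueError, match="span"):
        assign_aetiology(_finding(genes=("SPAST", "COL4A1")), GENES)
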