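"""Cohort-level statistics: diagnostic yield, enrichment, association tests.

Percentages are rounded half-up to one decimal, matching the convention
of clinical-yield reporting (24.7, 4.7, 13.5 ...). The trio-enrichment
test is an upper-tail hypergeometric probability P(X >= k): the chance of
observing at least the seen number of diagnosed trios when drawing the
trio subset from the cohort without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .types import SamplePhenotype


def pct(k: int, n: int) -> float:
    """Percentage k/n rounded half-up to one decimal place."""
    if n == 0:
        raise ZeroDivisionError("percentage of an empty denominator")
    return float((Decimal(100 * k) / Decimal(n)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP))


MECHANISMS = ("ad_missense", "ad_lof", "ar", "mt", "xl", "cnv", "blended")


@dataclass
class YieldSummary:
    n_cohort: int
    n_diagnosed: int
    n_cnv_diagnosed: int
    n_snv_diagnosed: int
    n_causative: int
    n_risk_factor: int
    n_vus_intolerant: int
    aetiology_counts: dict = field(default_factory=dict)
    mechanism_counts: dict = field(default_factory=dict)

    @property
    def n_autosomal_dominant(self) -> int:
        return (self.mechanism_counts.get("ad_missense", 0)
                + self.mechanism_counts.get("ad_lof", 0))

    def percentages(self) -> dict:
        """One-decimal percentages re-derived from the counts."""
        out = {
            "diagnosed_pct_of_cohort": pct(self.n_diagnosed, self.n_cohort),
            "cnv_diagnosed_pct_of_cohort": pct(self.n_cnv_diagnosed,
                                               self.n_cohort),
            "snv_diagnosed_pct_of_cohort": pct(self.n_snv_diagnosed,
                                               self.n_cohort),
            "vus_intolerant_pct_of_cohort": pct(self.n_vus_intolerant,
                                                self.n_cohort),
        }
        if self.n_diagnosed:
            out["ad_pct_of_diagnosed"] = pct(self.n_autosomal_dominant,
                                             self.n_diagnosed)
            for g, k in sorted(self.aetiology_counts.items()):
                out[f"{g}_pct_of_diagnosed"] = pct(k, self.n_diagnosed)
        return out


def yield_summary(findings, cohort_ids,
                  mechanism_map: Optional[dict] = None,
                  vus_intolerant_ids=()) -> YieldSummary:
    """Summarize per-individual diagnostic yield from classified findings.

    An individual is diagnosed iff they carry >= 1 finding with clinical
    significance causative or risk_factor; CNV-diagnosed iff any such
    finding is a CNV. ``mechanism_map`` optionally supplies per-individual
    mechanism labels (ad_missense, ad_lof, ar, mt, xl, cnv, blended) for
    the mechanism breakdown.
    """
    cohort = set(cohort_ids)
    per_individual: dict[str, list] = {}
    for f in findings:
        if f.case_id not in cohort:
            raise ValueError(
                f"finding for {f.case_id!r} but individual absent from cohort")
        per_individual.setdefault(f.case_id, []).append(f)

    diagnosed, cnv_diag, causative, risk = set(), set(), set(), set()
    aetiology_counts: dict[str, int] = {}
    for cid, fs in per_individual.items():
        reportable = [f for f in fs if f.clinical_significance in
                      ("causative", "risk_factor")]
        if not reportable:
            continue
        diagnosed.add(cid)
        if any(f.clinical_significance == "causative" for f in reportable):
            causative.add(cid)
        else:
            risk.add(cid)
        if any(f.is_cnv for f in reportable):
            cnv_diag.add(cid)
        aet = next((f.aetiology for f in reportable if f.aetiology), None)
        if aet:
            aetiology_counts[aet] = aetiology_counts.get(aet, 0) + 1

    mechanism_counts: dict[str, int] = {}
    for cid in diagnosed:
        mech = (mechanism_map or {}).get(cid)
        if mech:
            mechanism_counts[mech] = mechanism_counts.get(mech, 0) + 1

    return YieldSummary(
        n_cohort=len(cohort),
        n_diagnosed=len(diagnosed),
        n_cnv_diagnosed=len(cnv_diag),
        n_snv_diagnosed=len(diagnosed) - len(cnv_diag),
        n_causative=len(causative),
        n_risk_factor=len(risk),
        n_vus_intolerant=len(set(vus_intolerant_ids)),
        aetiology_counts=aetiology_counts,
        mechanism_counts=mechanism_counts,
    )


@dataclass
class EnrichmentResult:
    fold: float
    p_value: float
    N: int
    K: int
    n: int
    k: int


def trio_enrichment(N: int, K: int, n: int, k: int) -> EnrichmentResult:
    """Hypergeometric enrichment of diagnoses in a cohort subset.

    fold = (k/n) / (K/N); p = P(X >= k) for X ~ Hypergeom(N, K, n),
    the upper-tail probability of observing at least k diagnosed
    individuals among the n subset members.
    """
    if not (0 <= k <= min(n, K) and 0 < n <= N and 0 < K <= N):
        raise ValueError(f"invalid hypergeometric bounds N={N} K={K} n={n} k={k}")
    fold = (k / n) / (K / N)
    p = float(sps.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(fold=fold, p_value=p, N=N, K=K, n=n, k=k)


def comorbidity_code(phenotype: SamplePhenotype) -> int:
    """Number of reported comorbidities (autism, developmental delay,
    epilepsy), coded 0-3. Requires all three flags non-missing."""
    flags = phenotype.comorbidity_flags
    if any(f is None for f in flags):
        raise ValueError(
            f"{phenotype.sample_id}: comorbidity flags incomplete; "
            "exclude the individual upstream")
    return sum(bool(f) for f in flags)


@dataclass
class StatResult:
    name: str
    estimate: float
    p_value: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    df: Optional[int] = None


def chisq_association(table, correction: bool = False) -> StatResult:
    """Pearson chi-square test of independence on an r x c count table."""
    arr = np.asarray(table, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative counts in contingency table")
    row_sums = arr.sum(axis=1)
    col_sums = arr.sum(axis=0)
    for i, s in enumerate(row_sums):
        if s == 0:
            raise ValueError(f"degenerate contingency table: row {i} is all zero")
    for j, s in enumerate(col_sums):
        if s == 0:
            raise ValueError(f"degenerate contingency table: column {j} is all zero")
    chi2, p, dof, _ = sps.chi2_contingency(arr, correction=correction)
    return StatResult(name="chi_square", estimate=float(chi2),
                      p_value=float(p), df=int(dof))


class SeparationError(RuntimeError):
    pass


def logistic_fit(outcome: Sequence[int], covariates,
                 names: Optional[Sequence[str]] = None) -> list[StatResult]:
    """Maximum-likelihood logistic regression; per-covariate OR with Wald CI.

    ``covariates`` is an (n, p) array-like; ``names`` labels its columns.
    Returns one result per covariate: OR = exp(beta), 95% CI =
    exp(beta +/- 1.96 SE), Wald p-value. Perfect separation or
    non-convergence raises, naming the offending covariate.
    """
    y = np.asarray(outcome, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    if len(names) != p:
        raise ValueError("names length mismatch")
    for j in range(p):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"covariate {names[j]!r} is constant")
    if n <= p + 1:
        raise ValueError("more covariates than the sample supports")
    design = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, design)
    try:
        res = model.fit(disp=False, maxiter=50, tol=1e-8)
    except Exception as exc:  # statsmodels PerfectSeparationError etc.
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    params = res.params[1:]
    bse = res.bse[1:]
    pvals = res.pvalues[1:]
    out = []
    for j in range(p):
        if not np.isfinite(bse[j]) or bse[j] > 1e3:
            raise SeparationError(
                f"covariate {names[j]!r}: unstable estimate "
                "(separation or non-convergence)")
        out.append(StatResult(
            name=names[j],
            estimate=float(np.exp(params[j])),
            ci_low=float(np.exp(params[j] - 1.96 * bse[j])),
            ci_high=float(np.exp(params[j] + 1.96 * bse[j])),
            p_value=float(pvals[j])))
    return out
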