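"""Wet-lab validation arithmetic: qPCR copy number, MLPA, XCI skewing.

qPCR relative quantification uses the 2^-ddCt method with a reference
locus and a calibrator sample; diploid copy number is 2 x RQ. Standard-
curve amplification efficiency comes from the slope of Ct on log10 input
(a perfectly doubling reaction has slope -1/log10(2) ~ -3.3219, i.e.
efficiency 1.0). MLPA uses double normalization: target/reference peak
ratio within each sample, then division by the median intra-sample ratio
of reference samples. X-inactivation skewing follows the standard HUMARA
correction: post-digestion peak heights are corrected for per-allele PCR
bias using the undigested run, and skew is the larger corrected fraction.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class QPCRResult:
    delta_ct_sample: float
    delta_ct_calibrator: float
    ddct: float
    rq: float
    copy_number: float


def qpcr_copy_number(ct_target_sample: float, ct_ref_sample: float,
                     ct_target_cal: float, ct_ref_cal: float) -> QPCRResult:
    """Copy number of a target locus by the 2^-ddCt method.

    dCt = Ct(target) - Ct(reference) per sample; ddCt = dCt(sample) -
    dCt(calibrator); RQ = 2^-ddCt; copy number = 2 x RQ (calibrator
    assumed diploid at the target). Ct values are replicate means.
    """
    d_sample = ct_target_sample - ct_ref_sample
    d_cal = ct_target_cal - ct_ref_cal
    ddct = d_sample - d_cal
    rq = 2.0 ** (-ddct)
    return QPCRResult(delta_ct_sample=d_sample, delta_ct_calibrator=d_cal,
                      ddct=ddct, rq=rq, copy_number=2.0 * rq)


def qpcr_efficiency(dilution_points: list[tuple[float, float]]) -> float:
    """Amplification efficiency from a standard curve.

    ``dilution_points`` are (log10 input mass, Ct) pairs, >= 3 points with
    strictly decreasing input. Efficiency = 10^(-1/slope) - 1 where slope
    is the least-squares slope of Ct on log10(input); slope -3.3219 is
    perfect doubling (efficiency 1.0). A non-negative slope means the
    reaction did not amplify.
    """
    if len(dilution_points) < 3:
        raise ValueError("standard curve needs >= 3 dilution points")
    x = np.array([p[0] for p in dilution_points], dtype=float)
    y = np.array([p[1] for p in dilution_points], dtype=float)
    if not all(x[i] > x[i + 1] for i in range(len(x) - 1)):
        raise ValueError("dilution inputs must be strictly decreasing")
    slope = np.polyfit(x, y, 1)[0]
    if slope >= 0:
        raise ValueError(f"non-amplifying standard curve (slope {slope:.3f})")
    return float(10.0 ** (-1.0 / slope) - 1.0)


@dataclass
class MLPAResult:
    intra_ratio: float
    normalized_ratio: float
    copy_call: str          # "0" | "1" | "2" | "3+"


def mlpa_normalize(target_peak: float, ref_peak: float,
                   reference_sample_ratios: list[float],
                   thresholds: tuple = (0.25, 0.75, 1.25)) -> MLPAResult:
    """Double normalization of an MLPA target probe.

    intra_ratio = target peak / reference probe peak within the sample;
    normalized_ratio = intra_ratio / median intra-sample ratio across the
    reference (control) samples — the assay design uses five of them.
    Copy call thresholds default to midpoints between the expected ratios
    for 0, 1, 2 and 3 copies.
    """
    if target_peak <= 0 or ref_peak <= 0:
        raise ValueError("peak heights must be positive")
    if any(r <= 0 for r in reference_sample_ratios):
        raise ValueError("reference sample ratios must be positive")
    if len(reference_sample_ratios) != 5:
        warnings.warn(
            f"{len(reference_sample_ratios)} reference samples "
            "(assay design uses 5)", stacklevel=2)
    intra = target_peak / ref_peak
    norm = intra / statistics.median(reference_sample_ratios)
    lo, mid, hi = thresholds
    if norm < lo:
        call = "0"
    elif norm < mid:
        call = "1"
    elif norm <= hi:
        call = "2"
    else:
        call = "3+"
    return MLPAResult(intra_ratio=intra, normalized_ratio=norm,
                      copy_call=call)


@dataclass
class XCIResult:
    undigested_peaks: dict
    digested_peaks: dict
    corrected_fractions: dict
    skew_percent: float


def xci_skew(undigested: dict, digested: dict) -> XCIResult:
    """X-inactivation skew at an informative polymorphic locus.

    Methylated (inactive-X) alleles survive methylation-sensitive
    digestion, so each allele's digested/undigested peak ratio estimates
    its inactivation share after correcting the PCR amplification bias
    measured in the undigested run. Corrected fractions sum to 1; skew is
    100 x the larger fraction (50 = random XCI, 100 = complete skewing).
    """
    if set(undigested) != set(digested) or len(undigested) != 2:
        raise ValueError("expect the same two alleles in both conditions")
    if any(h <= 0 for h in undigested.values()):
        raise ValueError("undigested peaks must be positive "
                         "(informative heterozygote)")
    if any(h < 0 for h in digested.values()):
        raise ValueError("digested peaks must be non-negative")
    factors = {a: digested[a] / undigested[a] for a in undigested}
    total = sum(factors.values())
    if total == 0:
        raise ValueError("both alleles absent after digestion: assay failure")
    fractions = {a: f / total for a, f in factors.items()}
    return XCIResult(undigested_peaks=dict(undigested),
                     digested_peaks=dict(digested),
                     corrected_fractions=fractions,
                     skew_percent=100.0 * max(fractions.values()))
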