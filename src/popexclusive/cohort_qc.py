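"""Cohort quality control: call-level masks, site filters, HWE, and relatedness.

Two QC regimes share this module and differ only in thresholds:

* **discovery** (WGS cohort): mask calls with DP < 10 or GQ < 50, then drop
  sites with call rate < 100%, then sites with HWE exact p < 1e-5;
* **validation** (WES cohort): call rate < 80% and the same HWE rule.

All thresholds are strict inequalities on the failing side: a call with
DP = 10 and GQ = 50 passes, a site with HWE p exactly 1e-5 is retained.

The Hardy-Weinberg test is the exact conditional test: given the allele
counts, sum the probabilities of all heterozygote configurations no more
probable than the observed one.  Relatedness uses the method-of-moments
estimator of IBD sharing probabilities (k0, k1, k2) from observed
identity-by-state counts and allele frequencies, projected to the simplex,
with PI_HAT = k1/2 + k2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotype_model import GenotypeCounts, GenotypeMatrix, VariantKey

__all__ = [
    "QcThresholds",
    "DISCOVERY_QC",
    "VALIDATION_QC",
    "HweResult",
    "RelatednessEstimate",
    "genotype_call_rate",
    "mask_low_quality_calls",
    "hwe_exact_test",
    "hwe_exact_p",
    "site_qc",
    "ibd_mom",
    "pairwise_relatedness",
    "select_unrelated",
]

logger = logging.getLogger(__name__)

DEFAULT_PI_HAT_MAX = 0.1875  # midpoint between 2nd- and 3rd-degree expectations


@dataclass(frozen=True)
class QcThresholds:
    """Thresholds for one QC regime; failing sides are strict inequalities."""

    min_depth: int = 10
    min_gq: int = 50
    min_call_rate: float = 1.0
    hwe_alpha: float = 1e-5

    def __post_init__(self) -> None:
        if self.min_depth < 0 or self.min_gq < 0:
            raise ValueError("depth/GQ thresholds must be non-negative")
        if not 0.0 <= self.min_call_rate <= 1.0:
            raise ValueError("min_call_rate must be in [0,1]")
        if not 0.0 < self.hwe_alpha <= 1.0:
            raise ValueError("hwe_alpha must be in (0,1]")


DISCOVERY_QC = QcThresholds(min_depth=10, min_gq=50, min_call_rate=1.0, hwe_alpha=1e-5)
VALIDATION_QC = QcThresholds(min_depth=10, min_gq=50, min_call_rate=0.8, hwe_alpha=1e-5)


@dataclass(frozen=True)
class HweResult:
    counts: GenotypeCounts
    p_value: float


@dataclass(frozen=True)
class RelatednessEstimate:
    sample_pair: tuple[str, str]
    k0: float
    k1: float
    k2: float
    n_sites: int = 0

    @property
    def pi_hat(self) -> float:
        return self.k1 / 2.0 + self.k2


# ---------------------------------------------------------------------------
# Call-level and site-level filters
# ---------------------------------------------------------------------------

def genotype_call_rate(gm: GenotypeMatrix, v: VariantKey) -> float:
    """Fraction of samples with a non-missing call at ``v``."""
    col = gm.dose[:, gm.variant_index(v)]
    return float(np.sum(col >= 0)) / gm.n_samples


def mask_low_quality_calls(gm: GenotypeMatrix, thr: QcThresholds) -> GenotypeMatrix:
    """Null calls with DP < min_depth or GQ < min_gq; absent fields pass.

    Merged VCFs frequently lack uniform DP/GQ, so an absent field is treated
    as passing (with a warning) rather than emptying the matrix.
    """
    dose = gm.dose.copy()
    if gm.dp is not None:
        dose[(gm.dp >= 0) & (gm.dp < thr.min_depth)] = -1
    elif thr.min_depth > 0:
        logger.warning("no DP field loaded; depth filter (min %d) not applied", thr.min_depth)
    if gm.gq is not None:
        dose[(gm.gq >= 0) & (gm.gq < thr.min_gq)] = -1
    elif thr.min_gq > 0:
        logger.warning("no GQ field loaded; GQ filter (min %d) not applied", thr.min_gq)
    return GenotypeMatrix(
        samples=list(gm.samples),
        variants=list(gm.variants),
        dose=dose,
        dp=None if gm.dp is None else gm.dp.copy(),
        gq=None if gm.gq is None else gm.gq.copy(),
        multiallelic=gm.multiallelic.copy(),
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def _het_probabilities(n_het: int, n_hom_ref: int, n_hom_alt: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional probabilities of every attainable heterozygote count.

    Returns (het_counts, probabilities) for the distribution of the number of
    heterozygotes given the observed allele counts, P(h) proportional to
    multinomial(n; h, hom_ref(h), hom_alt(h)) * 2^h.  Uses the stable
    ratio recurrence rather than factorials.
    """
    n = n_het + n_hom_ref + n_hom_alt
    rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    common = 2 * n - rare
    # attainable het counts share the parity of the rare-allele count
    hs = np.arange(rare % 2, rare + 1, 2)
    probs = np.empty(len(hs), dtype=float)
    # start at (approximately) the modal heterozygote count for stability
    mid = int(round(rare * common / (2.0 * n)))
    if mid % 2 != rare % 2:
        mid += 1
    mid = min(mid, rare)
    i_mid = int(np.searchsorted(hs, mid))
    probs[i_mid] = 1.0
    # going down: P(h-2)/P(h) = h(h-1) / (4 (hom_r(h)+1)(hom_a(h)+1))
    for i in range(i_mid, 0, -1):
        h = int(hs[i])
        hom_r = (rare - h) // 2
        hom_a = n - h - hom_r
        probs[i - 1] = probs[i] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_a + 1))
    # going up: P(h+2)/P(h) = 4 hom_r(h) hom_a(h) / ((h+1)(h+2))
    for i in range(i_mid, len(hs) - 1):
        h = int(hs[i])
        hom_r = (rare - h) // 2
        hom_a = n - h - hom_r
        probs[i + 1] = probs[i] * 4.0 * hom_r * hom_a / ((h + 1.0) * (h + 2.0))
    probs /= probs.sum()
    return hs, probs


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional HWE p-value for one genotype-count triple."""
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("HWE test needs at least one called genotype")
    hs, probs = _het_probabilities(n_het, n_hom_ref, n_hom_alt)
    p_obs = probs[int(np.searchsorted(hs, n_het))]
    # tolerance guards against ties lost to floating-point rounding
    p = float(probs[probs <= p_obs * (1.0 + 1e-10)].sum())
    return min(p, 1.0)


def hwe_exact_test(counts: GenotypeCounts) -> HweResult:
    """Exact HWE test on a site's genotype tallies (missing calls ignored)."""
    if counts.n_called < 1:
        raise ValueError("HWE test on an all-missing site")
    return HweResult(counts=counts, p_value=hwe_exact_p(counts.n_hom_ref, counts.n_het, counts.n_hom_alt))


# ---------------------------------------------------------------------------
# Site QC pipeline
# ---------------------------------------------------------------------------

def site_qc(gm: GenotypeMatrix, thr: QcThresholds) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply one QC regime: mask low-quality calls, then filter sites.

    Sites fail, in order of attribution, on call rate (after masking) and
    then on HWE (p strictly below ``hwe_alpha``).  Returns the surviving
    matrix and a per-site report with columns
    ``chrom pos ref alt fail_reason call_rate hwe_p`` (``fail_reason`` empty
    for survivors; ``hwe_p`` is NaN for sites already failed on call rate or
    with no called genotypes).
    """
    masked = mask_low_quality_calls(gm, thr)
    called = masked.dose >= 0
    call_rate = called.sum(axis=0) / masked.n_samples

    hwe_p = np.full(masked.n_variants, np.nan)
    reasons = [""] * masked.n_variants
    keep = []
    for j in range(masked.n_variants):
        if call_rate[j] < thr.min_call_rate:
            reasons[j] = "call_rate"
            continue
        col = masked.dose[:, j]
        n_called = int(called[:, j].sum())
        if n_called == 0:
            reasons[j] = "call_rate"
            continue
        p = hwe_exact_p(
            int(np.sum(col == 0)), int(np.sum(col == 1)), int(np.sum(col == 2))
        )
        hwe_p[j] = p
        if p < thr.hwe_alpha:
            reasons[j] = "hwe"
            continue
        keep.append(j)

    report = pd.DataFrame(
        {
            "chrom": [v.chrom for v in masked.variants],
            "pos": [v.pos for v in masked.variants],
            "ref": [v.ref for v in masked.variants],
            "alt": [v.alt for v in masked.variants],
            "fail_reason": reasons,
            "call_rate": call_rate,
            "hwe_p": hwe_p,
        }
    )
    return masked.take_variants(keep), report


# ---------------------------------------------------------------------------
# Relatedness: method-of-moments IBD
# ---------------------------------------------------------------------------

def _mom_k(
    d1: np.ndarray, d2: np.ndarray, p: np.ndarray, min_sites: int
) -> tuple[float, float, float, int]:
    ok = (d1 >= 0) & (d2 >= 0) & (p > 0.0) & (p < 1.0)
    n = int(ok.sum())
    if n < min_sites:
        raise ValueError(f"only {n} informative sites; need at least {min_sites}")
    d1, d2, p = d1[ok], d2[ok], p[ok]
    q = 1.0 - p
    ibs = 2 - np.abs(d1 - d2)
    n0 = float(np.sum(ibs == 0))
    n1 = float(np.sum(ibs == 1))
    n2 = float(np.sum(ibs == 2))

    # expected IBS-class probabilities conditional on IBD state
    e0_z0 = float(np.sum(2.0 * p**2 * q**2))
    e1_z0 = float(np.sum(4.0 * p**3 * q + 4.0 * p * q**3))
    e2_z0 = float(np.sum(p**4 + q**4 + 4.0 * p**2 * q**2))
    e1_z1 = float(np.sum(2.0 * p * q))
    e2_z1 = float(np.sum(p**2 + q**2))

    k0 = n0 / e0_z0 if e0_z0 > 0 else 0.0
    k1 = (n1 - k0 * e1_z0) / e1_z1 if e1_z1 > 0 else 0.0
    k2 = (n2 - k0 * e2_z0 - k1 * e2_z1) / n

    # project onto the probability simplex
    k = np.clip([k0, k1, k2], 0.0, 1.0)
    s = k.sum()
    k = k / s if s > 0 else np.array([1.0, 0.0, 0.0])
    return float(k[0]), float(k[1]), float(k[2]), n


def ibd_mom(
    gm: GenotypeMatrix,
    pair: tuple[str, str],
    ref_freqs: np.ndarray | None = None,
    min_sites: int = 200,
) -> RelatednessEstimate:
    """Method-of-moments IBD estimate for one sample pair.

    ``ref_freqs`` gives per-variant alternate-allele frequencies aligned to
    ``gm.variants``; by default they are estimated from the cohort itself.
    """
    i1, i2 = gm.sample_index(pair[0]), gm.sample_index(pair[1])
    if ref_freqs is None:
        ref_freqs = _cohort_freqs(gm)
    ref_freqs = np.asarray(ref_freqs, dtype=float)
    if ref_freqs.shape != (gm.n_variants,):
        raise ValueError("ref_freqs must align with gm.variants")
    k0, k1, k2, n = _mom_k(gm.dose[i1], gm.dose[i2], ref_freqs, min_sites)
    return RelatednessEstimate(sample_pair=(pair[0], pair[1]), k0=k0, k1=k1, k2=k2, n_sites=n)


def _cohort_freqs(gm: GenotypeMatrix) -> np.ndarray:
    called = gm.dose >= 0
    total = 2.0 * called.sum(axis=0)
    alt = np.where(called, gm.dose, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total > 0, alt / total, np.nan)


def pairwise_relatedness(
    gm: GenotypeMatrix,
    ref_freqs: np.ndarray | None = None,
    min_sites: int = 200,
) -> list[RelatednessEstimate]:
    """MoM IBD for every sample pair, with cohort frequencies by default."""
    if ref_freqs is None:
        ref_freqs = _cohort_freqs(gm)
    out = []
    for s1, s2 in combinations(gm.samples, 2):
        out.append(ibd_mom(gm, (s1, s2), ref_freqs=ref_freqs, min_sites=min_sites))
    return out


def select_unrelated(
    estimates: Iterable[RelatednessEstimate],
    pi_hat_max: float = DEFAULT_PI_HAT_MAX,
    samples: Sequence[str] | None = None,
) -> set[str]:
    """Greedy unrelated-sample selection.

    Repeatedly removes the sample participating in the most pairs with
    PI_HAT >= ``pi_hat_max`` (ties broken by sample-id sort order) until no
    related pair remains.  ``samples`` optionally supplies the full candidate
    set so that samples appearing in no estimate are still returned.
    """
    estimates = list(estimates)
    kept: set[str] = set(samples) if samples is not None else set()
    for e in estimates:
        kept.update(e.sample_pair)
    edges = {
        frozenset(e.sample_pair) for e in estimates if e.pi_hat >= pi_hat_max
    }
    while edges:
        degree: dict[str, int] = {}
        for edge in edges:
            for s in edge:
                degree[s] = degree.get(s, 0) + 1
        worst = sorted(degree, key=lambda s: (-degree[s], s))[0]
        kept.discard(worst)
        edges = {e for e in edges if worst not in e}
    return kept
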