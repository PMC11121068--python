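"""Validation of candidate exclusive-common variants in a second cohort.

Candidates discovered in one cohort are re-examined in an independent cohort
of the same population: genotypes for the candidate sites are extracted,
sites failing the (relaxed) validation QC are set aside, and the rest are
confirmed when their validation-cohort MAF again exceeds the common
threshold.  For unconfirmed candidates a 2-fold concordance flag records
whether the two cohorts' MAFs nevertheless agree within a factor of two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .cohort_qc import QcThresholds, VALIDATION_QC, site_qc
from .frequency_catalogue import COMMON_MAF_THRESHOLD, FrequencyCatalogue, is_common_freq
from .genotype_model import GenotypeMatrix, VariantKey

__all__ = [
    "ValidationOutcome",
    "ValidationSummary",
    "extract_candidates",
    "validate_candidates",
    "exclusion_screen",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ValidationOutcome:
    variant: VariantKey
    status: str  # "excluded_qc" | "confirmed_common" | "not_validated" | "absent"
    maf_discovery: float | None = None
    maf_validation: float | None = None
    fold_concordant: bool | None = None


@dataclass
class ValidationSummary:
    n_candidates: int
    n_absent: int
    n_pass_qc: int
    n_confirmed: int
    n_not_validated: int
    n_fold_concordant: int
    null_proportion: float = 0.5
    binom_p: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None

    @property
    def proportion_confirmed(self) -> float:
        if self.n_pass_qc == 0:
            return float("nan")
        return self.n_confirmed / self.n_pass_qc


def extract_candidates(
    gm_validation: GenotypeMatrix, candidates: list[VariantKey]
) -> tuple[GenotypeMatrix, list[VariantKey]]:
    """Restrict the validation matrix to candidate sites; report absentees.

    Duplicate candidate keys are deduplicated (first occurrence wins) with a
    warning.  Returns (restricted matrix, absent candidates).
    """
    seen: set[VariantKey] = set()
    unique: list[VariantKey] = []
    for v in candidates:
        if v in seen:
            logger.warning("duplicate candidate %s deduplicated", v)
            continue
        seen.add(v)
        unique.append(v)

    idx, absent = [], []
    for v in unique:
        try:
            idx.append(gm_validation.variant_index(v))
        except KeyError:
            absent.append(v)
    return gm_validation.take_variants(idx), absent


def fold_change_concordant(maf_a: float, maf_b: float, max_fold: float = 2.0) -> bool | None:
    """Whether two MAFs differ by at most ``max_fold``; None when either is 0."""
    if maf_a <= 0.0 or maf_b <= 0.0:
        return None
    hi, lo = max(maf_a, maf_b), min(maf_a, maf_b)
    return hi / lo <= max_fold


def validate_candidates(
    gm_validation: GenotypeMatrix,
    candidates: list[VariantKey],
    discovery_catalogue: FrequencyCatalogue | None = None,
    thr: QcThresholds = VALIDATION_QC,
    threshold: float = COMMON_MAF_THRESHOLD,
    null_proportion: float = 0.5,
) -> tuple[list[ValidationOutcome], ValidationSummary]:
    """Run the validation regime on candidate variants.

    Candidates absent from the validation VCF get status ``absent``; sites
    failing validation QC get ``excluded_qc``; survivors are
    ``confirmed_common`` when their validation MAF exceeds ``threshold``,
    else ``not_validated`` with a 2-fold concordance flag against the
    discovery MAF (undefined when either MAF is zero).  The summary carries
    an exact binomial test of the confirmed proportion against
    ``null_proportion`` — a reporting convention, not an attempt to model a
    specific sampling null.
    """
    extracted, absent = extract_candidates(gm_validation, candidates)
    qcd, report = site_qc(extracted, thr)

    surviving = set(qcd.variants)
    maf_d = {}
    if discovery_catalogue is not None:
        for v in extracted.variants:
            f = discovery_catalogue.frequency(v)
            maf_d[v] = min(f, 1.0 - f)

    called = qcd.dose >= 0
    total = 2.0 * called.sum(axis=0)
    alt = np.where(called, qcd.dose, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(total > 0, alt / total, 0.0)
    maf_v = dict(zip(qcd.variants, np.minimum(freq, 1.0 - freq)))

    outcomes: list[ValidationOutcome] = []
    n_confirmed = n_not_validated = n_concordant = 0
    for v in absent:
        outcomes.append(ValidationOutcome(v, "absent", maf_discovery=maf_d.get(v)))
    for v in extracted.variants:
        if v not in surviving:
            outcomes.append(ValidationOutcome(v, "excluded_qc", maf_discovery=maf_d.get(v)))
            continue
        mv = float(maf_v[v])
        md = maf_d.get(v)
        if is_common_freq(mv, threshold):
            n_confirmed += 1
            outcomes.append(
                ValidationOutcome(v, "confirmed_common", maf_discovery=md, maf_validation=mv)
            )
        else:
            n_not_validated += 1
            conc = None if md is None else fold_change_concordant(md, mv)
            if conc:
                n_concordant += 1
            outcomes.append(
                ValidationOutcome(
                    v, "not_validated", maf_discovery=md, maf_validation=mv, fold_concordant=conc
                )
            )

    n_pass = n_confirmed + n_not_validated
    summary = ValidationSummary(
        n_candidates=len(absent) + extracted.n_variants,
        n_absent=len(absent),
        n_pass_qc=n_pass,
        n_confirmed=n_confirmed,
        n_not_validated=n_not_validated,
        n_fold_concordant=n_concordant,
        null_proportion=null_proportion,
    )
    if n_pass > 0:
        bt = binomtest(n_confirmed, n_pass, null_proportion)
        ci = bt.proportion_ci(confidence_level=0.95, method="exact")
        summary.binom_p = float(bt.pvalue)
        summary.ci_low = float(ci.low)
        summary.ci_high = float(ci.high)
    else:
        logger.warning("no candidates passed validation QC; proportions undefined")
    return outcomes, summary


def exclusion_screen(
    candidates: list[VariantKey], blocklist: set[VariantKey] | list[VariantKey]
) -> tuple[list[VariantKey], list[VariantKey]]:
    """Drop candidates present in a blocklist (e.g. disease-associated variants).

    Returns (surviving candidates, removed candidates).
    """
    block = set(blocklist)
    kept = [v for v in candidates if v not in block]
    removed = [v for v in candidates if v in block]
    return kept, removed


def outcomes_to_frame(outcomes: list[ValidationOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [o.variant.chrom for o in outcomes],
            "pos": [o.variant.pos for o in outcomes],
            "ref": [o.variant.ref for o in outcomes],
            "alt": [o.variant.alt for o in outcomes],
            "status": [o.status for o in outcomes],
            "maf_discovery": [o.maf_discovery for o in outcomes],
            "maf_validation": [o.maf_validation for o in outcomes],
            "fold_concordant": [o.fold_concordant for o in outcomes],
        }
    )
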