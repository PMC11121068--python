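"""Per-patient benchmark of frequency-based variant filtering.

For each patient the carried exonic SNVs (alt-allele dose >= 1) are filtered
against each frequency catalogue in turn: variants whose catalogue MAF
exceeds the common threshold are removed, variants absent from the catalogue
are retained (frequency-0 convention).  The benchmark reports the fraction
of each patient's variants that survive per catalogue, summarised as median
and quartiles — the catalogue matched to the patients' own population is
expected to be the most stringent filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frequency_catalogue import COMMON_MAF_THRESHOLD, FrequencyCatalogue, is_common_freq
from .genotype_model import GenotypeMatrix, VariantKey

__all__ = [
    "RetentionStats",
    "patient_variant_list",
    "filter_against_catalogue",
    "retention_benchmark",
]


@dataclass
class RetentionStats:
    """Per-patient retention fractions and per-catalogue summaries.

    ``per_patient`` is indexed by sample with columns
    (catalogue, one of n_input/n_retained/fraction_retained); ``summary`` has
    one row per catalogue with the median and quartiles of the retained
    fraction, sorted most-stringent (lowest median) first.
    """

    per_patient: pd.DataFrame
    summary: pd.DataFrame

    @property
    def stringency_order(self) -> list[str]:
        return list(self.summary.index)


def patient_variant_list(gm: GenotypeMatrix, sample: str) -> list[VariantKey]:
    """Variants the sample carries: non-missing dose >= 1."""
    i = gm.sample_index(sample)
    row = gm.dose[i]
    return [gm.variants[j] for j in np.flatnonzero(row >= 1)]


def filter_against_catalogue(
    variants: list[VariantKey],
    cat: FrequencyCatalogue,
    threshold: float = COMMON_MAF_THRESHOLD,
) -> list[VariantKey]:
    """Drop variants common (MAF > threshold) in the catalogue; keep the rest."""
    if not variants:
        return []
    f = cat.frequencies(variants, default=0.0)
    keep = ~is_common_freq(f, threshold)
    return [v for v, k in zip(variants, keep) if k]


def retention_benchmark(
    gm: GenotypeMatrix,
    samples: list[str],
    catalogues: list[FrequencyCatalogue],
    threshold: float = COMMON_MAF_THRESHOLD,
) -> RetentionStats:
    """Fraction of each patient's variants retained under each catalogue filter."""
    if not samples or not catalogues:
        raise ValueError("need at least one sample and one catalogue")

    # precompute per-catalogue common mask over the matrix's variants
    common_masks = {}
    for cat in catalogues:
        f = cat.frequencies(gm.variants, default=0.0)
        common_masks[cat.population_name] = is_common_freq(f, threshold)

    rows = []
    for s in samples:
        i = gm.sample_index(s)
        carried = gm.dose[i] >= 1
        n_input = int(carried.sum())
        for cat in catalogues:
            retained = carried & ~common_masks[cat.population_name]
            n_ret = int(retained.sum())
            rows.append(
                {
                    "sample": s,
                    "catalogue": cat.population_name,
                    "n_input": n_input,
                    "n_retained": n_ret,
                    "fraction_retained": n_ret / n_input if n_input else np.nan,
                }
            )
    per_patient = pd.DataFrame(rows).set_index(["sample", "catalogue"])

    summary = (
        per_patient.reset_index()
        .groupby("catalogue")["fraction_retained"]
        .agg(
            median="median",
            q1=lambda x: float(np.nanquantile(x, 0.25)),
            q3=lambda x: float(np.nanquantile(x, 0.75)),
        )
        .sort_values("median")
    )
    return RetentionStats(per_patient=per_patient, summary=summary)
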