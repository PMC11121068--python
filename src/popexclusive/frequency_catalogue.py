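"""Allele counting, minor allele frequency, and composite reference populations.

Two composite constructions are supported, mirroring how regional reference
panels are commonly assembled:

* **allele pooling** (:func:`pool_cohorts`): the combined alternate-allele
  count divided by the combined total allele count across cohorts — used to
  merge cohorts of raw genotypes (e.g. an Iberian panel with a national
  medical-genome panel into a single ``spain`` reference);
* **mean of population frequencies** (:func:`mean_population_frequency`):
  the unweighted arithmetic mean of per-population frequencies — used to
  summarise a many-population project (e.g. all 1KGP populations excluding
  the Iberian cohort) without letting large populations dominate.

A variant absent from a catalogue is treated as frequency 0 (rare) for
classification: absence from a large reference panel is evidence of rarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_model import GenotypeMatrix, VariantKey

__all__ = [
    "FrequencyCatalogue",
    "MafValue",
    "COMMON_MAF_THRESHOLD",
    "cohort_allele_counts",
    "maf",
    "pool_cohorts",
    "mean_population_frequency",
    "build_cohort_catalogue",
]

COMMON_MAF_THRESHOLD = 0.01  # common <=> MAF strictly above 1%

# Tie guard for the strict boundary: folding 1 - f in binary floating point
# can inflate a frequency that is exactly at the threshold (1 - 0.99 > 0.01);
# differences at or below this epsilon count as ties, i.e. rare.
_BOUNDARY_EPS = 1e-12


def is_common_freq(alt_freq, threshold: float = COMMON_MAF_THRESHOLD):
    """Common/rare verdict for alt frequencies (scalar or array): folded MAF
    strictly above the threshold, with a 1e-12 tie guard."""
    f = np.asarray(alt_freq, dtype=float)
    verdict = np.minimum(f, 1.0 - f) > threshold + _BOUNDARY_EPS
    return bool(verdict) if verdict.ndim == 0 else verdict


class MafValue:
    """Minor allele frequency min(f, 1-f) with its common/rare verdict."""

    __slots__ = ("maf", "is_common")

    def __init__(self, alt_freq: float, common_threshold: float = COMMON_MAF_THRESHOLD):
        if not 0.0 <= alt_freq <= 1.0:
            raise ValueError(f"alt_freq {alt_freq} outside [0,1]")
        self.maf = min(alt_freq, 1.0 - alt_freq)
        self.is_common = is_common_freq(alt_freq, common_threshold)

    def __repr__(self) -> str:
        tag = "common" if self.is_common else "rare"
        return f"MafValue(maf={self.maf:.5f}, {tag})"


def maf(alt_freq: float, common_threshold: float = COMMON_MAF_THRESHOLD) -> MafValue:
    """Fold an alternate-allele frequency to its MAF and classify common/rare."""
    return MafValue(alt_freq, common_threshold)


@dataclass
class FrequencyCatalogue:
    """Per-variant allele counts and frequencies for one (possibly composite) population.

    Backed by a DataFrame indexed by (chrom, pos, ref, alt) with columns
    ``alt_count``, ``total_count`` (NaN when only frequencies are known) and
    ``alt_freq``.
    """

    population_name: str
    data: pd.DataFrame

    @classmethod
    def from_arrays(
        cls,
        name: str,
        keys: Sequence[VariantKey],
        alt_count: np.ndarray,
        total_count: np.ndarray,
        alt_freq: np.ndarray,
    ) -> "FrequencyCatalogue":
        idx = pd.MultiIndex.from_tuples(keys, names=["chrom", "pos", "ref", "alt"])
        df = pd.DataFrame(
            {
                "alt_count": np.asarray(alt_count, dtype=float),
                "total_count": np.asarray(total_count, dtype=float),
                "alt_freq": np.asarray(alt_freq, dtype=float),
            },
            index=idx,
        )
        cat = cls(population_name=name, data=df)
        cat.validate()
        return cat

    @classmethod
    def from_mapping(
        cls, name: str, entries: Mapping[VariantKey, tuple[float | None, float | None, float]]
    ) -> "FrequencyCatalogue":
        keys = list(entries)
        ac = np.array([np.nan if entries[k][0] is None else entries[k][0] for k in keys])
        tc = np.array([np.nan if entries[k][1] is None else entries[k][1] for k in keys])
        fr = np.array([entries[k][2] for k in keys], dtype=float)
        return cls.from_arrays(name, keys, ac, tc, fr)

    def validate(self) -> None:
        ac = self.data["alt_count"].to_numpy()
        tc = self.data["total_count"].to_numpy()
        fr = self.data["alt_freq"].to_numpy()
        if np.any((fr < 0) | (fr > 1)):
            raise ValueError(f"catalogue {self.population_name}: frequency outside [0,1]")
        with_counts = ~np.isnan(tc)
        if np.any(ac[with_counts] > tc[with_counts]):
            raise ValueError(f"catalogue {self.population_name}: alt_count > total_count")
        derived = ac[with_counts] / tc[with_counts]
        if np.any(np.abs(derived - fr[with_counts]) > 1e-12):
            raise ValueError(
                f"catalogue {self.population_name}: alt_freq inconsistent with counts"
            )
        if self.data.index.has_duplicates:
            raise ValueError(f"catalogue {self.population_name}: duplicate variant keys")

    @property
    def has_counts(self) -> bool:
        return bool(len(self.data)) and not self.data["total_count"].isna().any()

    def __len__(self) -> int:
        return len(self.data)

    def __contains__(self, v: VariantKey) -> bool:
        return tuple(v) in self.data.index

    def keys(self) -> list[VariantKey]:
        return [VariantKey(*t) for t in self.data.index]

    def frequency(self, v: VariantKey, default: float = 0.0) -> float:
        """Alternate-allele frequency; absent variants default to 0 (rare)."""
        try:
            return float(self.data.at[tuple(v), "alt_freq"])
        except KeyError:
            return default

    def frequencies(self, keys: Sequence[VariantKey], default: float = 0.0) -> np.ndarray:
        """Vectorised frequency lookup over ``keys`` with the absence default."""
        reindexed = self.data["alt_freq"].reindex(pd.MultiIndex.from_tuples(keys))
        return reindexed.fillna(default).to_numpy()

    def counts(self, v: VariantKey) -> tuple[int, int] | None:
        try:
            row = self.data.loc[tuple(v)]
        except KeyError:
            return None
        if np.isnan(row["total_count"]):
            return None
        return int(row["alt_count"]), int(row["total_count"])

    def to_frame(self) -> pd.DataFrame:
        return self.data.reset_index()


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def cohort_allele_counts(gm: GenotypeMatrix, v: VariantKey) -> tuple[int, int]:
    """Alt and total allele counts at ``v`` over non-missing calls only."""
    col = gm.dose[:, gm.variant_index(v)]
    called = col >= 0
    n_called = int(np.sum(called))
    if n_called == 0:
        raise ValueError(f"variant {v}: no non-missing calls")
    return int(col[called].sum()), 2 * n_called


def _matrix_counts(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    called = gm.dose >= 0
    alt = np.where(called, gm.dose, 0).sum(axis=0)
    total = 2 * called.sum(axis=0)
    return alt.astype(float), total.astype(float)


def build_cohort_catalogue(gm: GenotypeMatrix, name: str) -> FrequencyCatalogue:
    """Catalogue with allele counts for every variant in a (QC'd) genotype matrix."""
    alt, total = _matrix_counts(gm)
    if np.any(total == 0):
        bad = gm.variants[int(np.flatnonzero(total == 0)[0])]
        raise ValueError(f"variant {bad}: no non-missing calls")
    return FrequencyCatalogue.from_arrays(
        name=name,
        keys=gm.variants,
        alt_count=alt,
        total_count=total,
        alt_freq=alt / total,
    )


def pool_cohorts(cats: Iterable[FrequencyCatalogue], name: str = "pooled") -> FrequencyCatalogue:
    """Pool cohorts by summing allele counts: sum(alt) / sum(total).

    Every input must carry counts.  A variant absent from one cohort
    contributes that cohort's modal total allele count as reference alleles
    when the cohort has a single site total (fully genotyped panel), else
    contributes nothing for that cohort.
    """
    cats = list(cats)
    if not cats:
        raise ValueError("no catalogues to pool")
    for c in cats:
        if not c.has_counts:
            raise ValueError(
                f"catalogue {c.population_name!r} is frequency-only; pooling needs counts"
            )
    # per-cohort implied total for absent variants: the unique per-site total
    # if the cohort has one (all sites genotyped in the same n), else 0
    implied: list[float] = []
    for c in cats:
        totals = c.data["total_count"].unique()
        implied.append(float(totals[0]) if len(totals) == 1 else 0.0)

    union = cats[0].data.index
    for c in cats[1:]:
        union = union.union(c.data.index)

    alt = np.zeros(len(union))
    total = np.zeros(len(union))
    for c, imp in zip(cats, implied):
        ac = c.data["alt_count"].reindex(union)
        tc = c.data["total_count"].reindex(union)
        alt += ac.fillna(0.0).to_numpy()
        total += tc.fillna(imp).to_numpy()
    if np.any(total == 0):
        raise ValueError("pooled catalogue has sites with zero total alleles")
    return FrequencyCatalogue.from_arrays(
        name=name,
        keys=[VariantKey(*t) for t in union],
        alt_count=alt,
        total_count=total,
        alt_freq=alt / total,
    )


def mean_population_frequency(
    cats: Iterable[FrequencyCatalogue],
    exclude: Iterable[str] = (),
    name: str = "popmean",
) -> FrequencyCatalogue:
    """Unweighted mean of per-population alt frequencies, after exclusions.

    Variants absent from a population contribute frequency 0 to the mean.
    The result is frequency-only (no pooled counts are implied).
    """
    exclude = set(exclude)
    kept = [c for c in cats if c.population_name not in exclude]
    if not kept:
        raise ValueError("no populations remain after exclusion")
    union = kept[0].data.index
    for c in kept[1:]:
        union = union.union(c.data.index)
    freq = np.zeros(len(union))
    for c in kept:
        freq += c.data["alt_freq"].reindex(union).fillna(0.0).to_numpy()
    freq /= len(kept)
    n = len(union)
    return FrequencyCatalogue.from_arrays(
        name=name,
        keys=[VariantKey(*t) for t in union],
        alt_count=np.full(n, np.nan),
        total_count=np.full(n, np.nan),
        alt_freq=freq,
    )
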