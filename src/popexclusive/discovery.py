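"""Cross-population classification of common variants and saturation analysis.

A variant is *exclusive-common* when its MAF exceeds the common threshold in
the target (regional) catalogue and does not exceed it in any reference
catalogue.  The upset category of a variant is the subset of panel
populations in which it is common, computed over the union of variant keys:
a variant absent from a catalogue counts as frequency 0 (rare) there.

The saturation (rarefaction) analysis asks how many individuals are needed
before the common-variant catalogue stops growing: for each cohort size n it
redraws random sample subsets, recomputes per-variant MAF on the subset
(without re-running site QC) and counts common variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .frequency_catalogue import COMMON_MAF_THRESHOLD, FrequencyCatalogue, is_common_freq
from .genotype_model import GenotypeMatrix, VariantKey

__all__ = [
    "PopulationPanel",
    "DiscoveryResult",
    "SaturationCurve",
    "classify_panel",
    "find_exclusive_common",
    "saturation_curve",
]


@dataclass
class PopulationPanel:
    """A target catalogue plus an ordered list of reference catalogues."""

    target: FrequencyCatalogue
    references: list[FrequencyCatalogue]

    def __post_init__(self) -> None:
        names = [self.target.population_name] + [r.population_name for r in self.references]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate population names in panel: {names}")

    @property
    def names(self) -> list[str]:
        return [self.target.population_name] + [r.population_name for r in self.references]


@dataclass
class DiscoveryResult:
    """Per-variant classification across a panel.

    ``table`` is indexed by (chrom, pos, ref, alt) with one boolean
    ``common_<population>`` column per panel member, the variant's ``category``
    (comma-joined names of populations where it is common, in panel order) and
    an ``exclusive`` flag (common in the target only).
    """

    panel_names: list[str]
    table: pd.DataFrame

    def category_counts(self) -> pd.Series:
        """Upset-plot counts: number of variants per common-population subset."""
        return self.table.groupby("category", sort=True).size()

    @property
    def exclusive_keys(self) -> list[VariantKey]:
        sub = self.table[self.table["exclusive"]]
        keys = [VariantKey(*t) for t in sub.index]
        return sorted(keys, key=lambda v: (_chrom_rank(v.chrom), v.pos, v.ref, v.alt))


def _chrom_rank(chrom: str) -> tuple[int, str]:
    return (int(chrom), "") if chrom.isdigit() else (100, chrom)


def classify_panel(
    panel: PopulationPanel, threshold: float = COMMON_MAF_THRESHOLD
) -> DiscoveryResult:
    """Classify every variant in the panel union as common/rare per population."""
    if not 0.0 < threshold < 0.5:
        raise ValueError(f"common threshold {threshold} outside (0, 0.5)")
    cats = [panel.target] + list(panel.references)
    union = cats[0].data.index
    for c in cats[1:]:
        union = union.union(c.data.index)

    table = pd.DataFrame(index=union)
    common_cols = []
    for c in cats:
        f = c.data["alt_freq"].reindex(union).fillna(0.0).to_numpy()
        col = f"common_{c.population_name}"
        table[col] = is_common_freq(f, threshold)
        common_cols.append(col)

    names = panel.names
    flags = table[common_cols].to_numpy()
    table["category"] = [
        ",".join(n for n, f in zip(names, row) if f) for row in flags
    ]
    table["exclusive"] = flags[:, 0] & ~flags[:, 1:].any(axis=1)
    table.index.names = ["chrom", "pos", "ref", "alt"]
    return DiscoveryResult(panel_names=names, table=table)


def find_exclusive_common(
    panel: PopulationPanel, threshold: float = COMMON_MAF_THRESHOLD
) -> list[VariantKey]:
    """Variants common in the target and rare in every reference, sorted by position."""
    return classify_panel(panel, threshold).exclusive_keys


@dataclass
class SaturationCurve:
    """Common-variant counts on random sample subsets of increasing size."""

    sizes: list[int]
    mean_counts: list[float]
    sd_counts: list[float]
    full_count: int
    plateau_n: int | None
    replicates: int
    per_replicate: dict[int, list[int]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n": self.sizes, "mean_common": self.mean_counts, "sd_common": self.sd_counts}
        )


def saturation_curve(
    gm: GenotypeMatrix,
    sizes: list[int],
    replicates: int = 25,
    seed: int | np.random.Generator = 0,
    threshold: float = COMMON_MAF_THRESHOLD,
    rel_tol: float = 0.0,
) -> SaturationCurve:
    """Rarefaction of the common-variant count over random subsamples.

    For each n in ``sizes`` draw ``replicates`` subsets without replacement,
    recompute MAF per variant on the subset and count MAF > ``threshold``.
    ``plateau_n`` is the smallest n whose mean count is within
    ``rel_tol * full_count`` of the full-cohort count (default: no new
    variants at all).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    for n in sizes:
        if not 1 <= n <= gm.n_samples:
            raise ValueError(f"subset size {n} outside [1, {gm.n_samples}]")

    dose = gm.dose
    full_count = _count_common(dose, threshold)

    sizes = sorted(sizes)
    means, sds = [], []
    per_rep: dict[int, list[int]] = {}
    for n in sizes:
        counts = []
        for _ in range(replicates if n < gm.n_samples else 1):
            idx = rng.choice(gm.n_samples, size=n, replace=False)
            counts.append(_count_common(dose[idx], threshold))
        if n == gm.n_samples:
            counts = counts * replicates
        per_rep[n] = counts
        means.append(float(np.mean(counts)))
        sds.append(float(np.std(counts)))

    plateau_n = None
    for n, m in zip(sizes, means):
        if abs(m - full_count) <= rel_tol * full_count:
            plateau_n = n
            break
    return SaturationCurve(
        sizes=sizes,
        mean_counts=means,
        sd_counts=sds,
        full_count=full_count,
        plateau_n=plateau_n,
        replicates=replicates,
        per_replicate=per_rep,
    )


def _count_common(dose: np.ndarray, threshold: float) -> int:
    called = dose >= 0
    total = 2.0 * called.sum(axis=0)
    alt = np.where(called, dose, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(total > 0, alt / total, 0.0)
    return int(np.sum(is_common_freq(f, threshold)))
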