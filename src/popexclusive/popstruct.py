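"""Population structure: genotype PCA and Weir-Cockerham F_ST.

PCA uses the Patterson standardization: each site is centred by its mean
dose and scaled by sqrt(2 p (1-p)) with p the sample alternate-allele
frequency; missing doses are mean-imputed before scaling.  Components come
from an SVD of the standardized matrix with a deterministic sign convention
(the largest-magnitude loading of each component is made positive).

F_ST uses the Weir & Cockerham (1984) variance-component estimator for a
biallelic locus: per site the among-population (a), among-individual-within-
population (b) and within-individual (c) components are computed from sample
sizes, allele frequencies and observed heterozygosities; the reported
pairwise estimate is the ratio of sums over sites, sum(a) / sum(a+b+c)
(the "weighted" mean), with the per-site mean of a/(a+b+c) also reported.
Negative estimates are reported as computed, flagged, and not clamped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .genotype_model import GenotypeCounts, GenotypeMatrix

__all__ = [
    "PcaResult",
    "FstEstimate",
    "standardize_genotypes",
    "pca",
    "weir_cockerham_site",
    "mean_pairwise_fst",
    "fst_between",
]

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    coordinates: np.ndarray  # (n_samples, n_components)
    explained_variance: np.ndarray  # fractions, non-increasing
    loadings: np.ndarray  # (n_sites_kept, n_components)
    kept_sites: np.ndarray  # indices of polymorphic sites used
    n_components: int


@dataclass(frozen=True)
class FstEstimate:
    population_pair: tuple[str, str]
    mean_fst: float  # ratio of sums (weighted)
    mean_fst_per_site: float  # mean of per-site ratios
    n_sites_used: int
    negative: bool = False


def standardize_genotypes(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Patterson-standardized dose matrix; monomorphic/all-missing sites dropped.

    Returns (matrix, kept column indices).
    """
    dose = gm.dose.astype(float)
    missing = dose < 0
    dose[missing] = np.nan
    n_called = (~missing).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n_called > 0, np.nansum(dose, axis=0) / n_called, np.nan)
    p = mean / 2.0
    poly = (p > 0.0) & (p < 1.0) & ~np.isnan(p)
    if not np.all(poly):
        logger.warning("dropping %d monomorphic or all-missing sites", int(np.sum(~poly)))
    dose = dose[:, poly]
    mean = mean[poly]
    p = p[poly]
    dose = np.where(np.isnan(dose), mean, dose)
    return (dose - mean) / np.sqrt(2.0 * p * (1.0 - p)), np.flatnonzero(poly)


def pca(gm: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """PCA of the standardized genotype matrix via SVD."""
    if gm.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    x, kept = standardize_genotypes(gm)
    if x.shape[1] < 1:
        raise ValueError("no polymorphic sites for PCA")
    x = x - x.mean(axis=0)  # re-centre after imputation
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    k = min(n_components, rank)
    if k < n_components:
        logger.warning("degenerate rank %d < %d requested components", rank, n_components)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # sign convention: largest-magnitude loading positive
    for i in range(k):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    ev = s**2
    total_var = float(np.sum(x**2))
    return PcaResult(
        coordinates=u * s,
        explained_variance=ev / total_var if total_var > 0 else ev,
        loadings=vt.T,
        kept_sites=kept,
        n_components=k,
    )


def weir_cockerham_site(counts_by_pop: list[GenotypeCounts]) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) per-site variance components (a, b, c).

    ``a`` is the among-population component, ``b`` among individuals within
    populations, ``c`` within individuals.  A site monomorphic across all
    populations returns (0, 0, 0) and should be excluded from ratios.
    """
    counts = [c for c in counts_by_pop if c.n_called > 0]
    r = len(counts)
    if r < 2:
        raise ValueError("need at least 2 populations with called genotypes")
    n_i = np.array([c.n_called for c in counts], dtype=float)
    p_i = np.array([c.alt_count / c.total_count for c in counts])
    h_i = np.array([c.n_het / c.n_called for c in counts])

    n_total = n_i.sum()
    n_bar = n_total / r
    p_bar = float(np.sum(n_i * p_i) / n_total)
    if p_bar <= 0.0 or p_bar >= 1.0:
        return (0.0, 0.0, 0.0)
    n_c = (n_total - np.sum(n_i**2) / n_total) / (r - 1.0)
    s2 = float(np.sum(n_i * (p_i - p_bar) ** 2) / ((r - 1.0) * n_bar))
    h_bar = float(np.sum(n_i * h_i) / n_total)

    a = (n_bar / n_c) * (
        s2
        - (1.0 / (n_bar - 1.0))
        * (p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        p_bar * (1.0 - p_bar)
        - ((r - 1.0) / r) * s2
        - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
    )
    c = h_bar / 2.0
    return (float(a), float(b), float(c))


def _pop_counts(gm: GenotypeMatrix, sample_idx: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorised per-site genotype tallies for one population subset."""
    dose = gm.dose[sample_idx]
    called = dose >= 0
    n_called = called.sum(axis=0).astype(float)
    n_het = (dose == 1).sum(axis=0).astype(float)
    alt = np.where(called, dose, 0).sum(axis=0).astype(float)
    return n_called, n_het, alt


def fst_between(
    gm: GenotypeMatrix,
    populations: dict[str, list[str]],
    pair: tuple[str, str],
) -> FstEstimate:
    """Weir-Cockerham F_ST between two populations of one genotype matrix."""
    comps = _wc_components_vectorised(gm, [populations[pair[0]], populations[pair[1]]])
    a, b, c = comps
    denom = a + b + c
    usable = denom > 0
    n_used = int(usable.sum())
    if n_used == 0:
        raise ValueError(f"no usable (polymorphic) sites for pair {pair}")
    weighted = float(a[usable].sum() / denom[usable].sum())
    per_site = float(np.mean(a[usable] / denom[usable]))
    neg = weighted < 0
    if neg:
        logger.warning("negative F_ST %.5f for pair %s", weighted, pair)
    return FstEstimate(
        population_pair=pair,
        mean_fst=weighted,
        mean_fst_per_site=per_site,
        n_sites_used=n_used,
        negative=neg,
    )


def _wc_components_vectorised(
    gm: GenotypeMatrix, sample_groups: list[list[str]]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    r = len(sample_groups)
    idx = [np.array([gm.sample_index(s) for s in grp]) for grp in sample_groups]
    stats = [_pop_counts(gm, i) for i in idx]
    n_i = np.stack([s[0] for s in stats])  # (r, n_sites)
    het_i = np.stack([s[1] for s in stats])
    alt_i = np.stack([s[2] for s in stats])

    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = np.where(n_i > 0, alt_i / (2.0 * n_i), 0.0)
        h_i = np.where(n_i > 0, het_i / np.where(n_i > 0, n_i, 1), 0.0)

    n_total = n_i.sum(axis=0)
    ok = np.all(n_i > 0, axis=0) & (n_total / r > 1.0)
    n_bar = n_total / r
    with np.errstate(invalid="ignore", divide="ignore"):
        p_bar = (n_i * p_i).sum(axis=0) / n_total
        n_c = (n_total - (n_i**2).sum(axis=0) / n_total) / (r - 1.0)
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1.0) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / n_total

        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1.0))
            * (p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
        )
        c = h_bar / 2.0

    poly = (p_bar > 0.0) & (p_bar < 1.0) & ok
    zero = ~poly
    for arr in (a, b, c):
        arr[zero] = 0.0
        arr[np.isnan(arr)] = 0.0
    return a, b, c


def mean_pairwise_fst(
    gm: GenotypeMatrix,
    populations: dict[str, list[str]],
    pairs: list[tuple[str, str]] | None = None,
) -> list[FstEstimate]:
    """Pairwise weighted F_ST for every (or the given) population pair."""
    if pairs is None:
        pairs = list(combinations(sorted(populations), 2))
    return [fst_between(gm, populations, pair) for pair in pairs]
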