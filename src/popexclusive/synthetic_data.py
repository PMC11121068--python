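"""Structured-cohort simulator with known ground truth.

The generator emulates the study design the pipeline targets: a regional
discovery cohort (WGS, default 358 diploids) and a validation cohort (WES,
default 239 diploids) drawn from the same target population, plus reference
frequency panels — two Spanish-like cohorts to pool (defaults 107 and 267
diploids), a set of continental populations whose unweighted frequency mean
forms a "rest of the world excluding the target's sister cohort" reference,
and one large aggregate database.

Allele-frequency divergence follows the Balding-Nichols model: for ancestral
frequency p and divergence F, a population's frequency is Beta-distributed
with mean p and variance F p (1-p) (shapes p(1-F)/F and (1-p)(1-F)/F), so F
is directly comparable to the Weir-Cockerham F_ST the pipeline estimates.
Genotypes are Hardy-Weinberg draws, doses ~ Binomial(2, freq).  Per-call
read depth is negative-binomial, genotype quality is high with a small
low-GQ fraction, and calls go missing at a configurable rate.  A configured
number of sites is "spiked" to be common in the target population and rare
everywhere else; related sample pairs (duplicates, parent-offspring) can be
injected.  Everything is a pure function of (config, seed).

Sites are independent (no linkage disequilibrium) and there is no
demographic history or read-level error model.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .frequency_catalogue import FrequencyCatalogue, mean_population_frequency, pool_cohorts
from .genotype_model import (
    GenotypeMatrix,
    IntervalSet,
    VariantKey,
    write_catalogue,
    write_multisample_vcf,
)

__all__ = [
    "PopulationSpec",
    "SpikeConfig",
    "QualityConfig",
    "SimConfig",
    "TruthTable",
    "SimulatedStudy",
    "simulate_population_frequencies",
    "simulate_genotypes",
    "spike_exclusive_common",
    "attach_quality_and_missingness",
    "inject_related",
    "sample_count_catalogue",
    "simulate_study",
    "emit_fixture",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PopulationSpec:
    """One simulated population: label, Balding-Nichols divergence, cohort size."""

    label: str
    fst: float
    n_diploids: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.fst < 1.0:
            raise ValueError(f"divergence F must be in [0,1), got {self.fst}")
        if self.n_diploids < 1:
            raise ValueError("n_diploids must be positive")


@dataclass(frozen=True)
class SpikeConfig:
    """Spiked exclusive-common variants: common in the target, rare elsewhere."""

    n_exclusive: int = 40
    target_maf_range: tuple[float, float] = (0.03, 0.10)
    reference_maf_max: float = 0.002

    def __post_init__(self) -> None:
        lo, hi = self.target_maf_range
        if not 0.0 <= lo <= hi <= 0.5:
            raise ValueError("target_maf_range must satisfy 0 <= lo <= hi <= 0.5")
        if not 0.0 <= self.reference_maf_max <= 0.5:
            raise ValueError("reference_maf_max must be in [0, 0.5]")


@dataclass(frozen=True)
class QualityConfig:
    """Per-call DP/GQ noise and missingness.

    Defaults emulate well-covered 30x short-read data restricted to capture
    targets, where nearly every call passes DP >= 10 / GQ >= 50 and genuine
    missingness is rare; ``planted_low_dp_sites`` forces a visible fraction
    of low-depth calls at that many sites so call-rate filtering has known
    casualties.
    """

    dp_mean: float = 30.0
    dp_shape: float = 200.0  # negative-binomial size; large = near-Poisson
    gq_high: int = 99
    gq_low_rate: float = 1e-5  # fraction of calls with GQ drawn below 50
    missing_rate: float = 1e-5
    planted_low_dp_sites: int = 0
    planted_low_dp_fraction: float = 0.05


@dataclass(frozen=True)
class SimConfig:
    """Full study configuration; ``seed`` fixes all randomness."""

    n_sites: int = 2000
    ancestral_range: tuple[float, float] = (0.005, 0.5)
    target: str = "NAVARRE"
    # default panel structure mirrors the study: the regional WGS cohort, the
    # two Spanish panels that pool into "spain" (107 + 267 diploids), one
    # large aggregate database, and the 25 non-Iberian reference project
    # populations (~100 diploids each: 4 European, 4 admixed-American,
    # 5 South-Asian, 5 East-Asian, 7 African) whose unweighted frequency
    # mean forms the rest-of-world reference.  Divergence values are typical
    # continental-scale fixation indices for a south-European target.
    populations: tuple[PopulationSpec, ...] = (
        (
            PopulationSpec("NAVARRE", 0.0005, 358),
            PopulationSpec("IBS", 0.0005, 107),
            PopulationSpec("MGP", 0.001, 267),
            PopulationSpec("gnomAD", 0.01, 15691),
        )
        + tuple(PopulationSpec(lbl, 0.004, 100) for lbl in ("GBR", "TSI", "CEU"))
        + (PopulationSpec("FIN", 0.008, 100),)
        + tuple(PopulationSpec(lbl, 0.015, 100) for lbl in ("MXL", "PUR", "CLM", "PEL"))
        + tuple(PopulationSpec(lbl, 0.025, 100) for lbl in ("GIH", "PJL", "BEB", "STU", "ITU"))
        + tuple(PopulationSpec(lbl, 0.03, 100) for lbl in ("CHB", "JPT", "CHS", "CDX", "KHV"))
        + tuple(
            PopulationSpec(lbl, 0.045, 100)
            for lbl in ("YRI", "LWK", "GWD", "MSL", "ESN", "ASW", "ACB")
        )
    )
    kgp_labels: tuple[str, ...] = (
        "GBR", "TSI", "CEU", "FIN",
        "MXL", "PUR", "CLM", "PEL",
        "GIH", "PJL", "BEB", "STU", "ITU",
        "CHB", "JPT", "CHS", "CDX", "KHV",
        "YRI", "LWK", "GWD", "MSL", "ESN", "ASW", "ACB",
    )
    n_validation: int = 239
    spike: SpikeConfig = field(default_factory=SpikeConfig)
    quality: QualityConfig = field(default_factory=QualityConfig)
    related_pairs: tuple[tuple[str, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [p.label for p in self.populations]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate population labels")
        if self.target not in labels:
            raise ValueError(f"target {self.target!r} not among populations")
        if self.spike.n_exclusive > self.n_sites:
            raise ValueError("more spiked sites than sites")

    def population(self, label: str) -> PopulationSpec:
        for p in self.populations:
            if p.label == label:
                return p
        raise KeyError(label)


@dataclass
class TruthTable:
    """Ground truth of one simulated study.

    ``variants`` is indexed by (chrom, pos, ref, alt) with the ancestral
    frequency, one ``freq_<label>`` column per population, and ``spiked`` /
    ``planted_low_dp`` flags.  ``sample_population`` maps sample id to
    population label; ``related_pairs`` lists (relationship, sample_a,
    sample_b).
    """

    variants: pd.DataFrame
    sample_population: dict[str, str]
    related_pairs: list[tuple[str, str, str]]

    @property
    def spiked_keys(self) -> list[VariantKey]:
        return [VariantKey(*t) for t in self.variants.index[self.variants["spiked"]]]


def _variant_keys(n_sites: int, rng: np.random.Generator) -> list[VariantKey]:
    """Evenly spread synthetic SNV keys over the 22 autosomes."""
    keys = []
    per_chrom = -(-n_sites // 22)
    i = 0
    for chrom in range(1, 23):
        for k in range(per_chrom):
            if i >= n_sites:
                break
            pos = 10_000 + 100 * k
            ref, alt = rng.choice(4, size=2, replace=False)
            keys.append(VariantKey(str(chrom), pos, str(_BASES[ref]), str(_BASES[alt])))
            i += 1
    return keys


def simulate_population_frequencies(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, np.ndarray], TruthTable]:
    """Balding-Nichols per-population frequency vectors plus the truth table."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    lo, hi = cfg.ancestral_range
    ancestral = rng.uniform(lo, hi, size=cfg.n_sites)
    freqs: dict[str, np.ndarray] = {}
    for pop in cfg.populations:
        if pop.fst == 0.0:
            freqs[pop.label] = ancestral.copy()
        else:
            a = ancestral * (1.0 - pop.fst) / pop.fst
            b = (1.0 - ancestral) * (1.0 - pop.fst) / pop.fst
            freqs[pop.label] = rng.beta(a, b)

    keys = _variant_keys(cfg.n_sites, rng)
    df = pd.DataFrame(
        {"ancestral_freq": ancestral},
        index=pd.MultiIndex.from_tuples(keys, names=["chrom", "pos", "ref", "alt"]),
    )
    for label, f in freqs.items():
        df[f"freq_{label}"] = f
    df["spiked"] = False
    df["planted_low_dp"] = False
    truth = TruthTable(variants=df, sample_population={}, related_pairs=[])
    return freqs, truth


def spike_exclusive_common(
    freqs: dict[str, np.ndarray],
    truth: TruthTable,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> None:
    """Overwrite chosen sites to be common in the target, rare in the rest.

    Spiked sites avoid any already-planted QC-failure sites.  Mutates the
    frequency vectors and truth table in place.
    """
    n = cfg.spike.n_exclusive
    if n == 0:
        return
    eligible = np.flatnonzero(~truth.variants["planted_low_dp"].to_numpy())
    idx = rng.choice(eligible, size=n, replace=False)
    lo, hi = cfg.spike.target_maf_range
    target_f = rng.uniform(lo, hi, size=n)
    for label in freqs:
        if label == cfg.target:
            freqs[label][idx] = target_f
        else:
            freqs[label][idx] = rng.uniform(0.0, cfg.spike.reference_maf_max, size=n)
        truth.variants[f"freq_{label}"] = freqs[label]
    spiked = truth.variants["spiked"].to_numpy()
    spiked[idx] = True
    truth.variants["spiked"] = spiked


def simulate_genotypes(
    freqs: np.ndarray,
    n_diploids: int,
    rng: np.random.Generator,
    sample_prefix: str = "S",
    keys: list[VariantKey] | None = None,
) -> GenotypeMatrix:
    """HWE genotypes: doses ~ Binomial(2, freq) independently per sample."""
    freqs = np.asarray(freqs, dtype=float)
    dose = rng.binomial(2, freqs[None, :], size=(n_diploids, len(freqs))).astype(np.int8)
    if keys is None:
        keys = _variant_keys(len(freqs), np.random.default_rng(0))
    samples = [f"{sample_prefix}{i:04d}" for i in range(n_diploids)]
    return GenotypeMatrix(samples=samples, variants=list(keys), dose=dose)


def attach_quality_and_missingness(
    gm: GenotypeMatrix,
    quality: QualityConfig,
    rng: np.random.Generator,
    truth: TruthTable | None = None,
) -> GenotypeMatrix:
    """Draw per-call DP/GQ and apply missingness; optionally plant low-DP sites."""
    shape = gm.dose.shape
    p_nb = quality.dp_shape / (quality.dp_shape + quality.dp_mean)
    dp = rng.negative_binomial(quality.dp_shape, p_nb, size=shape).astype(np.int32)
    gq = np.full(shape, quality.gq_high, dtype=np.int32)
    low_gq = rng.random(shape) < quality.gq_low_rate
    gq[low_gq] = rng.integers(0, 50, size=int(low_gq.sum()))

    if quality.planted_low_dp_sites > 0:
        candidates = np.arange(gm.n_variants)
        if truth is not None:
            spiked = truth.variants["spiked"].to_numpy()
            candidates = candidates[~spiked[: gm.n_variants]]
        sites = rng.choice(candidates, size=quality.planted_low_dp_sites, replace=False)
        for j in sites:
            hit = rng.random(gm.n_samples) < quality.planted_low_dp_fraction
            if not hit.any():
                hit[rng.integers(gm.n_samples)] = True
            dp[hit, j] = rng.integers(0, 10, size=int(hit.sum()))
        if truth is not None:
            planted = truth.variants["planted_low_dp"].to_numpy()
            planted[sites] = True
            truth.variants["planted_low_dp"] = planted

    dose = gm.dose.copy()
    dose[rng.random(shape) < quality.missing_rate] = -1
    return GenotypeMatrix(
        samples=list(gm.samples),
        variants=list(gm.variants),
        dose=dose,
        dp=dp,
        gq=gq,
        multiallelic=gm.multiallelic.copy(),
    )


def inject_related(
    gm: GenotypeMatrix,
    related_pairs: tuple[tuple[str, int], ...],
    rng: np.random.Generator,
    truth: TruthTable | None = None,
) -> GenotypeMatrix:
    """Overwrite samples to create duplicate or parent-offspring pairs.

    ``duplicate``: a sample's doses are copied over another's.
    ``parent_offspring``: the second sample becomes a Mendelian child of the
    first sample and a third (unmodified) sample, one transmitted allele per
    site per parent.  Used sample slots are disjoint across pairs.
    """
    dose = gm.dose.copy()
    pool = list(range(gm.n_samples))
    pairs: list[tuple[str, str, str]] = []
    for relationship, count in related_pairs:
        for _ in range(count):
            if relationship == "duplicate":
                if len(pool) < 2:
                    raise ValueError("not enough samples for related pairs")
                a, b = pool.pop(0), pool.pop(0)
                dose[b] = dose[a]
                pairs.append(("duplicate", gm.samples[a], gm.samples[b]))
            elif relationship == "parent_offspring":
                if len(pool) < 3:
                    raise ValueError("not enough samples for related pairs")
                p1, p2, child = pool.pop(0), pool.pop(0), pool.pop(0)
                miss = (dose[p1] < 0) | (dose[p2] < 0)
                allele1 = rng.random(gm.n_variants) < dose[p1].clip(0) / 2.0
                allele2 = rng.random(gm.n_variants) < dose[p2].clip(0) / 2.0
                child_dose = (allele1.astype(np.int8) + allele2.astype(np.int8))
                child_dose[miss] = -1
                dose[child] = child_dose
                pairs.append(("parent_offspring", gm.samples[p1], gm.samples[child]))
                pool.insert(0, p2)  # second parent stays available as unrelated-ish
            else:
                raise ValueError(f"unknown relationship {relationship!r}")
    if truth is not None:
        truth.related_pairs.extend(pairs)
    return GenotypeMatrix(
        samples=list(gm.samples),
        variants=list(gm.variants),
        dose=dose,
        dp=None if gm.dp is None else gm.dp.copy(),
        gq=None if gm.gq is None else gm.gq.copy(),
        multiallelic=gm.multiallelic.copy(),
    )


def sample_count_catalogue(
    label: str,
    freqs: np.ndarray,
    n_diploids: int,
    keys: list[VariantKey],
    rng: np.random.Generator,
) -> FrequencyCatalogue:
    """Reference panel as sampled allele counts: alt ~ Binomial(2N, freq)."""
    total = 2 * n_diploids
    alt = rng.binomial(total, np.asarray(freqs, dtype=float))
    return FrequencyCatalogue.from_arrays(
        name=label,
        keys=keys,
        alt_count=alt.astype(float),
        total_count=np.full(len(keys), float(total)),
        alt_freq=alt / total,
    )


@dataclass
class SimulatedStudy:
    """In-memory bundle of one simulated study."""

    config: SimConfig
    truth: TruthTable
    discovery: GenotypeMatrix
    validation: GenotypeMatrix
    references: dict[str, FrequencyCatalogue]  # spain, <kgp-mean>, gnomAD
    per_population: dict[str, FrequencyCatalogue]
    targets: IntervalSet

    def true_exclusive_keys(self, threshold: float = 0.01) -> list[VariantKey]:
        """Variants genuinely exclusive-common under the *true* frequencies.

        Applies the same composite constructions the pipeline uses — allele
        pooling for ``spain`` (weighted by panel allele totals) and the
        unweighted mean for the multi-population reference — to the
        simulator's true per-population frequencies.  The spiked sites are a
        subset; boundary sites can be genuinely exclusive by drift alone.
        """
        from .frequency_catalogue import is_common_freq

        tv = self.truth.variants
        f_target = tv[f"freq_{self.config.target}"].to_numpy()
        exclusive = is_common_freq(f_target, threshold)

        if "freq_IBS" in tv.columns and "freq_MGP" in tv.columns:
            w_ibs = 2.0 * self.config.population("IBS").n_diploids
            w_mgp = 2.0 * self.config.population("MGP").n_diploids
            f_spain = (
                w_ibs * tv["freq_IBS"].to_numpy() + w_mgp * tv["freq_MGP"].to_numpy()
            ) / (w_ibs + w_mgp)
            exclusive &= ~is_common_freq(f_spain, threshold)
        if self.config.kgp_labels:
            f_kgp = (
                tv[[f"freq_{lbl}" for lbl in self.config.kgp_labels]]
                .to_numpy()
                .mean(axis=1)
            )
            exclusive &= ~is_common_freq(f_kgp, threshold)
        if "freq_gnomAD" in tv:
            exclusive &= ~is_common_freq(tv["freq_gnomAD"].to_numpy(), threshold)
        return [VariantKey(*t) for t in tv.index[exclusive]]


def simulate_study(cfg: SimConfig) -> SimulatedStudy:
    """Simulate the full study: cohorts, reference catalogues, ground truth.

    The discovery and validation cohorts are both drawn from the target
    population's frequency vector.  References are built exactly the way the
    pipeline composes real panels: ``spain`` by pooling the allele counts of
    the two Spanish-like panels, ``KGP_noIBS`` as the unweighted mean of the
    continental populations' frequencies (the sister Spanish panel excluded),
    and ``gnomAD`` as one large count catalogue.
    """
    rng = np.random.default_rng(cfg.seed)
    freqs, truth = simulate_population_frequencies(cfg, rng)
    spike_exclusive_common(freqs, truth, cfg, rng)
    keys = [VariantKey(*t) for t in truth.variants.index]

    target_pop = cfg.population(cfg.target)
    discovery = simulate_genotypes(
        freqs[cfg.target], target_pop.n_diploids, rng, sample_prefix="DIS", keys=keys
    )
    discovery = attach_quality_and_missingness(discovery, cfg.quality, rng, truth)
    discovery = inject_related(discovery, cfg.related_pairs, rng, truth)
    for s in discovery.samples:
        truth.sample_population[s] = cfg.target

    validation = simulate_genotypes(
        freqs[cfg.target], cfg.n_validation, rng, sample_prefix="VAL", keys=keys
    )
    validation = attach_quality_and_missingness(validation, cfg.quality, rng)
    for s in validation.samples:
        truth.sample_population[s] = cfg.target

    per_pop: dict[str, FrequencyCatalogue] = {}
    for pop in cfg.populations:
        if pop.label == cfg.target:
            continue
        per_pop[pop.label] = sample_count_catalogue(
            pop.label, freqs[pop.label], pop.n_diploids, keys, rng
        )

    spain = pool_cohorts([per_pop["IBS"], per_pop["MGP"]], name="spain") if (
        "IBS" in per_pop and "MGP" in per_pop
    ) else None
    kgp = mean_population_frequency(
        [per_pop[lbl] for lbl in cfg.kgp_labels if lbl in per_pop],
        name="KGP_noIBS",
    ) if cfg.kgp_labels else None

    references: dict[str, FrequencyCatalogue] = {}
    if spain is not None:
        references["spain"] = spain
    if kgp is not None:
        references["KGP_noIBS"] = kgp
    if "gnomAD" in per_pop:
        references["gnomAD"] = per_pop["gnomAD"]

    targets = IntervalSet([(str(c), 0, 1_000_000_000) for c in range(1, 23)])
    return SimulatedStudy(
        config=cfg,
        truth=truth,
        discovery=discovery,
        validation=validation,
        references=references,
        per_population=per_pop,
        targets=targets,
    )


def emit_fixture(cfg: SimConfig, outdir: str | os.PathLike) -> dict[str, str]:
    """Write a complete on-disk fixture: VCFs, BED, reference TSVs, truth TSVs.

    Returns a name -> path mapping.  Fully reproducible under ``cfg.seed``.
    """
    study = simulate_study(cfg)
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    paths["discovery_vcf"] = os.path.join(outdir, "discovery.vcf")
    write_multisample_vcf(study.discovery, paths["discovery_vcf"])
    paths["validation_vcf"] = os.path.join(outdir, "validation.vcf")
    write_multisample_vcf(study.validation, paths["validation_vcf"])

    paths["targets_bed"] = os.path.join(outdir, "targets.bed")
    with open(paths["targets_bed"], "w") as fh:
        for chrom, start, end in study.targets.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")

    for name, cat in {**study.references, **study.per_population}.items():
        p = os.path.join(outdir, f"{name}.freq.tsv")
        write_catalogue(cat, p)
        paths[f"catalogue_{name}"] = p

    paths["truth_variants"] = os.path.join(outdir, "truth_variants.tsv")
    study.truth.variants.reset_index().to_csv(paths["truth_variants"], sep="\t", index=False)
    paths["truth_samples"] = os.path.join(outdir, "truth_samples.tsv")
    pd.DataFrame(
        {"sample": list(study.truth.sample_population),
         "population": list(study.truth.sample_population.values())}
    ).to_csv(paths["truth_samples"], sep="\t", index=False)
    paths["truth_related"] = os.path.join(outdir, "truth_related.tsv")
    pd.DataFrame(
        study.truth.related_pairs, columns=["relationship", "sample_a", "sample_b"]
    ).to_csv(paths["truth_related"], sep="\t", index=False)
    return paths


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The study-scale default configuration with a chosen seed."""
    return replace(SimConfig(), seed=seed, **overrides)
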