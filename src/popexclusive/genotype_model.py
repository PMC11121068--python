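"""Domain types and I/O for multi-sample VCFs, BED intervals and frequency tables.

Coordinate conventions
----------------------
VCF positions are 1-based and all internal coordinates are kept 1-based.
BED input is 0-based half-open, converted on read: a 1-based position ``p``
lies inside BED interval ``(chrom, start, end)`` iff ``start < p <= end``.
Chromosome labels are normalised by stripping a leading ``chr``.

Missing-data conventions
------------------------
Any genotype containing a missing allele (``./.``, ``./1`` half-calls) is a
missing call.  Phased separators are treated identically to unphased ones:
only the alternate-allele dose matters.  Multiallelic records are retained on
read but flagged, and removed by :func:`select_biallelic_autosomal_snvs`
rather than split, so that allele counts are never redistributed.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantKey",
    "GenotypeCall",
    "GenotypeCounts",
    "GenotypeMatrix",
    "IntervalSet",
    "read_multisample_vcf",
    "write_multisample_vcf",
    "read_bed_intervals",
    "select_biallelic_autosomal_snvs",
    "read_frequency_table",
    "write_catalogue",
]

AUTOSOMES = frozenset(str(i) for i in range(1, 23))
_BASES = frozenset("ACGT")

MISSING = -1  # sentinel for missing dose / absent DP / absent GQ


def normalize_chrom(label: str) -> str:
    """Strip a leading ``chr`` prefix and map ``M`` to ``MT``."""
    c = label[3:] if label.lower().startswith("chr") else label
    return "MT" if c == "M" else c


class VariantKey(NamedTuple):
    """Identity of a variant: chromosome, 1-based position, ref and alt alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str


class GenotypeCall(NamedTuple):
    """A single diploid call: alt-allele dose (0/1/2 or None) with optional DP/GQ."""

    allele_dose: int | None
    depth: int | None = None
    quality: int | None = None


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype tallies at one site; the basis of call rate, HWE and allele counts."""

    n_hom_ref: int
    n_het: int
    n_hom_alt: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        if min(self.n_hom_ref, self.n_het, self.n_hom_alt, self.n_missing) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n_called(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt

    @property
    def n_samples(self) -> int:
        return self.n_called + self.n_missing

    @property
    def alt_count(self) -> int:
        return self.n_het + 2 * self.n_hom_alt

    @property
    def total_count(self) -> int:
        return 2 * self.n_called


@dataclass
class GenotypeMatrix:
    """Samples x variants grid of diploid calls with per-call DP/GQ.

    ``dose`` holds alternate-allele counts (0, 1, 2) with ``-1`` for missing;
    ``dp``/``gq`` hold per-call depth and genotype quality with ``-1`` where
    the field was absent in the source VCF. ``multiallelic`` flags records that
    carried more than one ALT allele.
    """

    samples: list[str]
    variants: list[VariantKey]
    dose: np.ndarray  # (n_samples, n_variants) int8
    dp: np.ndarray | None = None  # (n_samples, n_variants) int32, -1 = absent
    gq: np.ndarray | None = None
    multiallelic: np.ndarray | None = None  # (n_variants,) bool
    _index: dict[VariantKey, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        ns, nv = len(self.samples), len(self.variants)
        if self.dose.shape != (ns, nv):
            raise ValueError(
                f"dose grid shape {self.dose.shape} does not match "
                f"{ns} samples x {nv} variants"
            )
        if len(set(self.samples)) != ns:
            raise ValueError("duplicate sample identifiers")
        if len(set(self.variants)) != nv:
            raise ValueError("duplicate variant keys")
        if self.multiallelic is None:
            self.multiallelic = np.zeros(nv, dtype=bool)
        self._index = {v: i for i, v in enumerate(self.variants)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, v: VariantKey) -> int:
        try:
            return self._index[v]
        except KeyError:
            raise KeyError(f"variant {v.chrom}:{v.pos}:{v.ref}>{v.alt} not in matrix") from None

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in matrix") from None

    def call(self, sample: str, v: VariantKey) -> GenotypeCall:
        i, j = self.sample_index(sample), self.variant_index(v)
        d = int(self.dose[i, j])
        dp = None if self.dp is None or self.dp[i, j] < 0 else int(self.dp[i, j])
        gq = None if self.gq is None or self.gq[i, j] < 0 else int(self.gq[i, j])
        return GenotypeCall(None if d < 0 else d, dp, gq)

    def genotype_counts(self, v: VariantKey) -> GenotypeCounts:
        col = self.dose[:, self.variant_index(v)]
        return GenotypeCounts(
            n_hom_ref=int(np.sum(col == 0)),
            n_het=int(np.sum(col == 1)),
            n_hom_alt=int(np.sum(col == 2)),
            n_missing=int(np.sum(col < 0)),
        )

    def take_variants(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[i] for i in idx],
            dose=self.dose[:, idx].copy(),
            dp=None if self.dp is None else self.dp[:, idx].copy(),
            gq=None if self.gq is None else self.gq[:, idx].copy(),
            multiallelic=self.multiallelic[idx].copy(),
        )

    def take_samples(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            variants=list(self.variants),
            dose=self.dose[idx, :].copy(),
            dp=None if self.dp is None else self.dp[idx, :].copy(),
            gq=None if self.gq is None else self.gq[idx, :].copy(),
            multiallelic=self.multiallelic.copy(),
        )


@dataclass
class IntervalSet:
    """Genomic intervals in 0-based half-open coordinates, queryable per chromosome.

    Overlapping intervals are merged internally; membership is their union.
    """

    intervals: list[tuple[str, int, int]]
    _merged: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(f"interval {chrom}:{start}-{end} has start >= end")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.intervals:
            by_chrom.setdefault(normalize_chrom(chrom), []).append((start, end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            starts = np.array([m[0] for m in merged], dtype=np.int64)
            ends = np.array([m[1] for m in merged], dtype=np.int64)
            self._merged[chrom] = (starts, ends)

    def __len__(self) -> int:
        return len(self.intervals)

    def contains(self, chrom: str, pos: int | np.ndarray) -> bool | np.ndarray:
        """Whether 1-based position(s) fall inside the interval union."""
        entry = self._merged.get(normalize_chrom(chrom))
        pos = np.asarray(pos)
        if entry is None:
            res = np.zeros(pos.shape, dtype=bool)
            return bool(res) if res.ndim == 0 else res
        starts, ends = entry
        # 1-based p is inside (s, e] half-open 0-based iff s < p <= e
        j = np.searchsorted(starts, pos - 1, side="right") - 1
        inside = (j >= 0) & (pos <= ends[np.clip(j, 0, len(ends) - 1)])
        return bool(inside) if inside.ndim == 0 else inside


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_multisample_vcf(path: str | os.PathLike, fields: Iterable[str] = ("DP", "GQ")) -> GenotypeMatrix:
    """Load a multi-sample VCF into a :class:`GenotypeMatrix`.

    ``GT`` is mandatory; per-genotype keys named in ``fields`` (``DP``, ``GQ``)
    are loaded when present in the file.  Half-calls and ``./.`` become missing;
    multiallelic records are kept but flagged.
    """
    from cyvcf2 import VCF

    fields = set(fields)
    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"VCF {path} has no sample columns; GT data required")

    has_dp = "DP" in fields and any(h["ID"] == "DP" for h in _format_headers(vcf))
    has_gq = "GQ" in fields and any(h["ID"] == "GQ" for h in _format_headers(vcf))

    variants: list[VariantKey] = []
    doses: list[np.ndarray] = []
    dps: list[np.ndarray] = []
    gqs: list[np.ndarray] = []
    multi: list[bool] = []
    seen: set[VariantKey] = set()
    ns = len(samples)

    for lineno, rec in enumerate(vcf, start=1):
        if "GT" not in rec.FORMAT:
            raise ValueError(
                f"VCF record {rec.CHROM}:{rec.POS} (record {lineno}) lacks a GT field"
            )
        alt = rec.ALT[0] if rec.ALT else "."
        key = VariantKey(normalize_chrom(rec.CHROM), int(rec.POS), rec.REF, alt)
        if key in seen:
            raise ValueError(f"duplicate variant record {key} at record {lineno}")
        seen.add(key)
        variants.append(key)
        multi.append(len(rec.ALT) > 1)

        gt = np.asarray(rec.genotype.array())  # (ns, ploidy+1); last col = phasing
        alleles = gt[:, :-1]
        missing = np.any(alleles < 0, axis=1)
        dose = np.sum(alleles > 0, axis=1).astype(np.int8)
        dose[missing] = MISSING
        doses.append(dose)

        if has_dp:
            raw = rec.format("DP")
            if raw is None:
                dps.append(np.full(ns, MISSING, dtype=np.int32))
            else:
                d = raw.reshape(ns).astype(np.int64)
                # htslib encodes missing integers as large negative fill values
                dps.append(np.where(d < 0, MISSING, d).astype(np.int32))
        if has_gq:
            q = np.asarray(rec.gt_quals)
            q = np.where(np.isnan(q) | (q < 0), MISSING, q).astype(np.int32)
            gqs.append(q)

    dose = np.array(doses, dtype=np.int8).T if doses else np.zeros((ns, 0), dtype=np.int8)
    return GenotypeMatrix(
        samples=samples,
        variants=variants,
        dose=dose,
        dp=np.array(dps, dtype=np.int32).T if dps else None,
        gq=np.array(gqs, dtype=np.int32).T if gqs else None,
        multiallelic=np.array(multi, dtype=bool),
    )


def _format_headers(vcf) -> list[dict]:
    out = []
    for h in vcf.header_iter():
        try:
            if h.type == "FORMAT":
                out.append(h.info())
        except Exception:
            continue
    return out


def write_multisample_vcf(gm: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a VCF 4.2 with GT (and DP/GQ when the matrix carries them)."""
    fmt_keys = ["GT"]
    if gm.dp is not None:
        fmt_keys.append("DP")
    if gm.gq is not None:
        fmt_keys.append("GQ")

    chrom_order: list[str] = []
    for v in gm.variants:
        if v.chrom not in chrom_order:
            chrom_order.append(v.chrom)

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if gm.dp is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if gm.gq is not None:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        for c in chrom_order:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.samples) + "\n")
        gt_str = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
        for j, v in enumerate(gm.variants):
            cells = []
            for i in range(gm.n_samples):
                parts = [gt_str[int(gm.dose[i, j])]]
                if gm.dp is not None:
                    d = int(gm.dp[i, j])
                    parts.append("." if d < 0 else str(d))
                if gm.gq is not None:
                    q = int(gm.gq[i, j])
                    parts.append("." if q < 0 else str(q))
                cells.append(":".join(parts))
            row = [v.chrom, str(v.pos), ".", v.ref, v.alt, ".", "PASS", ".",
                   ":".join(fmt_keys)] + cells
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

def read_bed_intervals(path: str | os.PathLike) -> IntervalSet:
    """Read a BED3+ file into an :class:`IntervalSet` (0-based half-open)."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            intervals.append((chrom, start, end))
    return IntervalSet(intervals)


# ---------------------------------------------------------------------------
# Site-class selection
# ---------------------------------------------------------------------------

def select_biallelic_autosomal_snvs(gm: GenotypeMatrix, targets: IntervalSet) -> GenotypeMatrix:
    """Keep biallelic autosomal SNVs inside the target intervals, order preserved.

    A variant survives iff its chromosome is 1..22, ref and alt are single
    bases in {A,C,G,T}, the record was not multiallelic, and its position lies
    inside the target interval union.
    """
    keep = []
    for j, v in enumerate(gm.variants):
        if gm.multiallelic[j]:
            continue
        if v.chrom not in AUTOSOMES:
            continue
        if len(v.ref) != 1 or len(v.alt) != 1:
            continue
        if v.ref not in _BASES or v.alt not in _BASES or v.ref == v.alt:
            continue
        if not targets.contains(v.chrom, v.pos):
            continue
        keep.append(j)
    return gm.take_variants(keep)


# ---------------------------------------------------------------------------
# Frequency tables
# ---------------------------------------------------------------------------

_CAT_COLUMNS = ["chrom", "pos", "ref", "alt", "alt_count", "total_count", "freq"]


def read_frequency_table(path: str | os.PathLike, name: str | None = None):
    """Read a frequency-catalogue TSV into a :class:`FrequencyCatalogue`.

    Accepts either allele counts (``alt_count``/``total_count``), a bare
    ``freq`` column, or both; counts take precedence and the derived frequency
    is validated against them.
    """
    from .frequency_catalogue import FrequencyCatalogue

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    required = {"chrom", "pos", "ref", "alt"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    has_counts = {"alt_count", "total_count"}.issubset(df.columns) and not (
        df["alt_count"].isna().all() or df["total_count"].isna().all()
    )
    if not has_counts and "freq" not in df.columns:
        raise ValueError(f"{path}: needs alt_count/total_count or freq columns")

    df["chrom"] = df["chrom"].map(normalize_chrom)
    keys = list(zip(df["chrom"], df["pos"].astype(int), df["ref"], df["alt"]))
    if len(set(keys)) != len(keys):
        raise ValueError(f"{path}: duplicate variant keys")

    if has_counts:
        ac = df["alt_count"].to_numpy(dtype=float)
        tc = df["total_count"].to_numpy(dtype=float)
        if np.any(np.isnan(ac) != np.isnan(tc)):
            raise ValueError(f"{path}: alt_count/total_count must be present together")
        bad = (~np.isnan(ac)) & ((ac < 0) | (tc <= 0) | (ac > tc))
        if np.any(bad):
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: invalid counts {ac[i]:.0f}/{tc[i]:.0f} at row {i + 1}"
            )
        freq = np.where(np.isnan(ac), np.nan, ac / np.where(tc > 0, tc, 1))
        if "freq" in df.columns:
            given = df["freq"].to_numpy(dtype=float)
            freq = np.where(np.isnan(freq), given, freq)
    else:
        ac = np.full(len(df), np.nan)
        tc = np.full(len(df), np.nan)
        freq = df["freq"].to_numpy(dtype=float)

    if np.any((freq < 0) | (freq > 1)):
        i = int(np.flatnonzero((freq < 0) | (freq > 1))[0])
        raise ValueError(f"{path}: frequency {freq[i]} outside [0,1] at row {i + 1}")

    cat_name = name if name is not None else os.path.splitext(os.path.basename(str(path)))[0]
    return FrequencyCatalogue.from_arrays(
        name=cat_name,
        keys=[VariantKey(c, int(p), r, a) for c, p, r, a in keys],
        alt_count=ac,
        total_count=tc,
        alt_freq=freq,
    )


def write_catalogue(cat, path: str | os.PathLike, decimals: int = 5) -> None:
    """Write a frequency catalogue as TSV; lossless round-trip with the reader.

    Catalogues with counts write both counts and the derived frequency;
    frequency-only catalogues leave the count columns empty.
    """
    df = cat.to_frame()
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"],
            "ref": df["ref"],
            "alt": df["alt"],
            "alt_count": df["alt_count"].map(
                lambda x: "" if pd.isna(x) else str(int(x))
            ),
            "total_count": df["total_count"].map(
                lambda x: "" if pd.isna(x) else str(int(x))
            ),
            # counts are authoritative when present (reader re-derives freq);
            # frequency-only rows keep full precision for lossless round trips
            "freq": [
                f"{f:.{decimals}f}" if not pd.isna(t) else f"{f:.17g}"
                for f, t in zip(df["alt_freq"], df["total_count"])
            ],
        }
    )
    out.to_csv(path, sep="\t", index=False)
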