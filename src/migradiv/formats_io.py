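"""File formats and genomic coordinate conventions.

All in-memory coordinates are 0-based half-open, the BED convention. VCF
positions (1-based) are converted on read and back on write. A VCF position
``p`` therefore falls in the window with index ``(p - 1) // size``.

Variant genotypes are stored as alternate-allele dosages per diploid sample:
0 (hom ref), 1 (het), 2 (hom alt), -1 (missing).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

#: canonical column order for window-statistic tables
WINDOW_STAT_COLUMNS = [
    "scaffold", "start", "end", "window_index", "partial",
    "n_snps", "n_callable", "fst", "pi_s", "pi_n",
    "tajima_d_s", "tajima_d_n", "dxy", "da",
    "pass_callable", "pass_snps",
]

METADATA_COLUMNS = [
    "sample", "site", "latitude", "longitude", "altitude", "sex",
    "d15n", "wing", "tarsus", "bill_head", "color",
]


class FormatError(ValueError):
    """Malformed input file or violated format invariant."""


@dataclass(frozen=True)
class ScaffoldInfo:
    length: int
    chromosome: str = "Un"
    offset: int = 0  # cumulative bp offset for concatenated plotting


@dataclass
class GenomeLayout:
    """Scaffold lengths plus chromosome assignment and plotting offsets.

    Scaffolds are kept in insertion order; offsets are cumulative over that
    order so a concatenated Manhattan-style x-axis is ``offset + position``.
    """

    scaffolds: dict[str, ScaffoldInfo] = field(default_factory=dict)

    @classmethod
    def from_lengths(cls, lengths: dict[str, int],
                     chromosomes: dict[str, str] | None = None) -> "GenomeLayout":
        layout = cls()
        offset = 0
        for name, length in lengths.items():
            if length <= 0:
                raise FormatError(f"scaffold {name!r} has non-positive length {length}")
            if name in layout.scaffolds:
                raise FormatError(f"duplicate scaffold {name!r}")
            chrom = (chromosomes or {}).get(name, "Un")
            layout.scaffolds[name] = ScaffoldInfo(length, chrom, offset)
            offset += length
        return layout

    def __contains__(self, name: str) -> bool:
        return name in self.scaffolds

    def __iter__(self):
        return iter(self.scaffolds)

    def length(self, name: str) -> int:
        return self.scaffolds[name].length

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.scaffolds.values())


@dataclass(frozen=True)
class Window:
    """Half-open genomic interval produced by tiling a scaffold from 0."""

    scaffold: str
    start: int
    end: int
    index: int
    partial: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def make_windows(layout: GenomeLayout, size: int = 10_000) -> list[Window]:
    """Tile every scaffold with non-overlapping windows of ``size`` bp.

    The final window of a scaffold may be shorter; it is emitted with
    ``partial=True`` so summaries can exclude it.
    """
    if size <= 0:
        raise ValueError(f"window size must be positive, got {size}")
    windows: list[Window] = []
    index = 0
    for name, info in layout.scaffolds.items():
        for start in range(0, info.length, size):
            end = min(start + size, info.length)
            windows.append(Window(name, start, end, index, partial=end - start < size))
            index += 1
    return windows


def window_index_of(pos0: np.ndarray, size: int) -> np.ndarray:
    """Window index within a scaffold for 0-based positions."""
    return np.asarray(pos0) // size


# ---------------------------------------------------------------------------
# Callable / exclusion interval masks
# ---------------------------------------------------------------------------

def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    if len(iv) == 0:
        return np.empty((0, 2), dtype=np.int64)
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    merged = [iv[0].tolist()]
    for start, end in iv[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return np.array(merged, dtype=np.int64)


@dataclass
class CallableMask:
    """Per-scaffold sets of merged, sorted half-open intervals.

    Used both for callable-site masks (positions where a polymorphism could
    have been detected) and for exclusion masks such as annotated repeats.
    """

    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, raw: dict[str, "np.ndarray | list"]) -> "CallableMask":
        out = {}
        for scaf, iv in raw.items():
            arr = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
            if np.any(arr[:, 1] <= arr[:, 0]):
                bad = arr[arr[:, 1] <= arr[:, 0]][0]
                raise FormatError(f"interval end <= start on {scaf}: {bad.tolist()}")
            out[scaf] = _merge_intervals(arr)
        return cls(out)

    @classmethod
    def full(cls, layout: GenomeLayout) -> "CallableMask":
        """Mask covering every position of every scaffold."""
        return cls({name: np.array([[0, info.length]], dtype=np.int64)
                    for name, info in layout.scaffolds.items()})

    @property
    def total(self) -> int:
        return int(sum((iv[:, 1] - iv[:, 0]).sum() for iv in self.intervals.values()))

    def callable_in(self, scaffold: str, start: int, end: int) -> int:
        """Number of masked positions overlapping [start, end)."""
        iv = self.intervals.get(scaffold)
        if iv is None or len(iv) == 0:
            return 0
        lo = np.maximum(iv[:, 0], start)
        hi = np.minimum(iv[:, 1], end)
        return int(np.clip(hi - lo, 0, None).sum())

    def window_counts(self, windows: list[Window]) -> np.ndarray:
        return np.array([self.callable_in(w.scaffold, w.start, w.end) for w in windows],
                        dtype=np.int64)

    def contains(self, scaffold: str, pos0: np.ndarray) -> np.ndarray:
        """Boolean membership for 0-based positions on one scaffold."""
        pos0 = np.atleast_1d(np.asarray(pos0, dtype=np.int64))
        iv = self.intervals.get(scaffold)
        if iv is None or len(iv) == 0:
            return np.zeros(len(pos0), dtype=bool)
        idx = np.searchsorted(iv[:, 0], pos0, side="right") - 1
        ok = idx >= 0
        ok[ok] &= pos0[ok] < iv[idx[ok], 1]
        return ok

    def subtract(self, other: "CallableMask") -> "CallableMask":
        """Remove ``other``'s intervals from this mask (e.g. repeat exclusion)."""
        out: dict[str, np.ndarray] = {}
        for scaf, iv in self.intervals.items():
            cut = other.intervals.get(scaf)
            if cut is None or len(cut) == 0:
                out[scaf] = iv.copy()
                continue
            pieces = []
            for start, end in iv:
                cursor = start
                for cs, ce in cut:
                    if ce <= cursor or cs >= end:
                        continue
                    if cs > cursor:
                        pieces.append([cursor, min(cs, end)])
                    cursor = max(cursor, ce)
                    if cursor >= end:
                        break
                if cursor < end:
                    pieces.append([cursor, end])
            out[scaf] = np.array(pieces, dtype=np.int64).reshape(-1, 2)
        return CallableMask(out)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for scaf, iv in self.intervals.items():
                for start, end in iv:
                    fh.write(f"{scaf}\t{start}\t{end}\n")


def read_intervals(path) -> CallableMask:
    """Read a BED (3+ columns, 0-based half-open) into a merged mask."""
    raw: dict[str, list] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >=3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if end <= start:
                raise FormatError(f"{path}: line {lineno}: end <= start ({start}, {end})")
            raw.setdefault(parts[0], []).append((start, end))
    return CallableMask.from_intervals(raw)


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

@dataclass
class VariantTable:
    """Sites x samples diploid genotype matrix with per-site metadata.

    ``pos0`` is 0-based; ``genotypes`` holds alt-allele dosages (0/1/2, -1
    missing). Multiallelic sites and indels are retained but flagged so the
    biallelic-SNP view used by all windowed statistics is well defined.
    """

    scaffold: np.ndarray          # str per site
    pos0: np.ndarray              # int64, 0-based
    ref: np.ndarray
    alt: np.ndarray               # comma-joined alternate alleles
    qual: np.ndarray              # float per site
    genotypes: np.ndarray         # (n_sites, n_samples) int8 dosage
    samples: list[str]
    depth: np.ndarray | None = None   # (n_sites, n_samples) int32, -1 missing
    populations: dict[str, str] = field(default_factory=dict)
    is_snp: np.ndarray | None = None
    is_biallelic: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.pos0)
        if self.is_snp is None:
            self.is_snp = np.ones(n, dtype=bool)
        if self.is_biallelic is None:
            self.is_biallelic = np.ones(n, dtype=bool)
        for scaf in np.unique(self.scaffold):
            p = self.pos0[self.scaffold == scaf]
            if np.any(np.diff(p) <= 0):
                raise FormatError(f"positions not strictly increasing on {scaf}")

    @property
    def n_sites(self) -> int:
        return len(self.pos0)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[n] for n in names], dtype=np.intp)

    def population_indices(self, label: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.samples)
                         if self.populations.get(s) == label], dtype=np.intp)

    def take_sites(self, mask_or_idx) -> "VariantTable":
        idx = np.asarray(mask_or_idx)
        return replace(
            self,
            scaffold=self.scaffold[idx],
            pos0=self.pos0[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            qual=self.qual[idx],
            genotypes=self.genotypes[idx],
            depth=None if self.depth is None else self.depth[idx],
            is_snp=self.is_snp[idx],
            is_biallelic=self.is_biallelic[idx],
        )

    def biallelic_snps(self) -> "VariantTable":
        """View restricted to biallelic SNPs (the windowed-statistics substrate)."""
        return self.take_sites(self.is_snp & self.is_biallelic)


def read_variant_table(path, population_map: dict[str, str] | None = None) -> VariantTable:
    """Read a VCF 4.x into a :class:`VariantTable` via cyvcf2.

    ``population_map`` maps sample id to a population label (e.g. southern /
    northern); every mapped sample must appear in the VCF header.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if population_map:
        unknown = sorted(set(population_map) - set(samples))
        if unknown:
            raise FormatError(f"{path}: samples in population map absent from VCF: {unknown}")

    scaf, pos0, ref, alt, qual = [], [], [], [], []
    snp_flags, bi_flags, gts, dps = [], [], [], []
    record_no = 0
    try:
        for v in vcf:
            record_no += 1
            scaf.append(v.CHROM)
            pos0.append(v.POS - 1)
            ref.append(v.REF)
            alts = v.ALT or []
            alt.append(",".join(alts))
            qual.append(np.nan if v.QUAL is None else float(v.QUAL))
            bi_flags.append(len(alts) == 1)
            snp_flags.append(len(v.REF) == 1 and all(len(a) == 1 for a in alts))
            # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            gts.append(np.array([0, 1, MISSING, 2], dtype=np.int8)[v.gt_types])
            dp = v.format("DP")
            if dp is not None:
                dp = dp.astype(np.int32).reshape(-1)
                dp[dp < 0] = MISSING
            dps.append(dp)
    except Exception as exc:  # cyvcf2 raises plain Exceptions on bad records
        if isinstance(exc, FormatError):
            raise
        raise FormatError(f"{path}: malformed VCF record (data line {record_no + 1}): {exc}") from exc

    if any(d is None for d in dps):
        depth = None
    else:
        depth = np.vstack(dps) if dps else np.empty((0, len(samples)), dtype=np.int32)
    return VariantTable(
        scaffold=np.array(scaf, dtype=object),
        pos0=np.array(pos0, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        qual=np.array(qual, dtype=float),
        genotypes=(np.vstack(gts) if gts else np.empty((0, len(samples)), dtype=np.int8)),
        samples=samples,
        depth=depth,
        populations=dict(population_map or {}),
        is_snp=np.array(snp_flags, dtype=bool),
        is_biallelic=np.array(bi_flags, dtype=bool),
    )


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_variant_table(table: VariantTable, path, layout: GenomeLayout | None = None) -> None:
    """Write a minimal VCF 4.2 (GT[:DP]) that round-trips through the reader."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=migradiv\n")
        if layout is not None:
            for name, info in layout.scaffolds.items():
                fh.write(f"##contig=<ID={name},length={info.length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        has_dp = table.depth is not None
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        fmt = "GT:DP" if has_dp else "GT"
        for i in range(table.n_sites):
            qual = table.qual[i]
            qual_s = "." if np.isnan(qual) else f"{qual:g}"
            cells = []
            for j in range(table.n_samples):
                g = _GT_STRINGS[int(table.genotypes[i, j])]
                if has_dp:
                    d = int(table.depth[i, j])
                    g = f"{g}:{d if d >= 0 else '.'}"
                cells.append(g)
            fh.write(f"{table.scaffold[i]}\t{table.pos0[i] + 1}\t.\t{table.ref[i]}\t"
                     f"{table.alt[i]}\t{qual_s}\tPASS\t.\t{fmt}\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Sample metadata and window-statistic tables
# ---------------------------------------------------------------------------

def read_sample_metadata(path) -> pd.DataFrame:
    """Read the sample-metadata TSV.

    Required columns: sample, site, latitude, longitude, altitude, sex, and
    the phenotypes d15n, wing, tarsus, bill_head, color. Missing phenotype
    cells are preserved as NaN; color scores must lie in 1..9 when present.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "site": str, "sex": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata columns: {missing}")
    dup = df["sample"][df["sample"].duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicate sample ids: {sorted(set(dup))}")
    color = df["color"].dropna()
    bad = color[(color < 1) | (color > 9)]
    if len(bad):
        raise FormatError(f"{path}: color scores outside 1-9: {sorted(set(bad))}")
    return df


def write_window_stats(table: pd.DataFrame, path) -> None:
    """Write a window-statistic table as TSV with fixed column order.

    Missing statistics (filtered windows) are written as NA; a write-read
    round trip reproduces the values exactly.
    """
    if len(table) == 0:
        raise FormatError("refusing to write an empty window-statistic table")
    cols = [c for c in WINDOW_STAT_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_window_stats(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
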