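"""Genomic coordinate types, peak and gene-model I/O, overlap algebra,
TSS association and annotation-category enrichment.

All coordinates are 0-based half-open internally (BED convention).  Inputs
in 1-based fully-closed convention (MACS ``.xls``-style tables) are
converted on read, so a single convention holds throughout the package.
Two intervals overlap iff they share at least one base pair; half-open
adjacency (``end == start``) is *not* an overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "CistromeSet",
    "PeakAssociation",
    "OverlapResult",
    "AnnotationResult",
    "read_peaks",
    "write_peaks",
    "read_refflat",
    "overlap_sets",
    "map_to_tss",
    "classify_annotation",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Share at least 1 bp with *other* (half-open semantics)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Peak:
    """A transcription-factor binding site called from ChIP-seq.

    ``score`` is the peak caller's significance score (MACS-style
    -10*log10(p-value), dimensionless); ``fold_enrichment`` is ChIP over
    control signal at the site; ``summit`` is the absolute position of
    maximal tag enrichment.
    """

    interval: GenomicInterval
    summit: int
    score: float = 0.0
    fold_enrichment: float = 0.0
    id: str = ""

    def __post_init__(self) -> None:
        if not self.interval.contains(self.summit):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"[{self.interval.start}, {self.interval.end})"
            )
        if self.score < 0:
            raise ValueError("score must be >= 0")
        if self.fold_enrichment < 0:
            raise ValueError("fold_enrichment must be >= 0")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class GeneModel:
    """A transcript model: symbol, strand, TSS and exon structure."""

    gene: str
    tss: int
    strand: str
    chrom: str
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def tx_start(self) -> int:
        if self.exons:
            return min(e.start for e in self.exons)
        return self.tss

    @property
    def tx_end(self) -> int:
        if self.exons:
            return max(e.end for e in self.exons)
        return self.tss + 1


class CistromeSet:
    """The genome-wide set of binding sites of a factor in one condition."""

    def __init__(self, label: str, peaks: Iterable[Peak]):
        self.label = label
        self.peaks: list[Peak] = list(peaks)
        ids = [p.id for p in self.peaks if p.id]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate peak ids in cistrome {label!r}")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __repr__(self) -> str:
        return f"CistromeSet({self.label!r}, n={len(self)})"

    def by_id(self) -> dict[str, Peak]:
        return {p.id: p for p in self.peaks}

    def tree(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees for overlap queries."""
        trees: dict[str, IntervalTree] = {}
        for p in self.peaks:
            trees.setdefault(p.chrom, IntervalTree()).addi(
                p.interval.start, p.interval.end, p
            )
        return trees


# ---------------------------------------------------------------------------
# I/O


def read_peaks(path: str | Path, dialect: str = "bed6+", label: str | None = None) -> CistromeSet:
    """Read a peak list into a :class:`CistromeSet`.

    Dialects
    --------
    ``bed6+``
        chrom, start, end, name, score, strand, then optionally
        fold_enrichment and summit offset (relative to start).  0-based
        half-open, as BED.
    ``macs-xls-like``
        chrom, start, end, length, summit_offset, tags, score,
        fold_enrichment — 1-based fully-closed coordinates, converted
        to 0-based half-open on read.  Header/comment lines skipped.
    """
    path = Path(path)
    if dialect not in ("bed6+", "macs-xls-like"):
        raise ValueError(f"unknown dialect {dialect!r}")
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if dialect == "bed6+":
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    name = fields[3] if len(fields) > 3 else f"peak{lineno}"
                    score = float(fields[4]) if len(fields) > 4 else 0.0
                    fe = float(fields[6]) if len(fields) > 6 else 0.0
                    summit = (
                        start + int(fields[7]) if len(fields) > 7
                        else (start + end) // 2
                    )
                else:
                    if fields[1] in ("start", ""):  # header row
                        continue
                    chrom = fields[0]
                    start = int(fields[1]) - 1  # 1-based closed -> 0-based
                    end = int(fields[2])
                    summit = start + int(fields[4])
                    score = float(fields[6])
                    fe = float(fields[7]) if len(fields) > 7 else 0.0
                    name = f"peak{lineno}"
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"{path}:{lineno}: malformed peak line: {exc}"
                ) from exc
            interval = GenomicInterval(chrom, start, end)
            if not interval.contains(summit):
                raise ValueError(
                    f"{path}:{lineno}: summit {summit} outside "
                    f"[{start}, {end})"
                )
            peaks.append(Peak(interval, summit, score, fe, name))
    if not peaks:
        logger.warning("no peaks read from %s", path)
    return CistromeSet(label or path.stem, peaks)


def write_peaks(cistrome: CistromeSet, path: str | Path) -> None:
    """Write a cistrome as BED6 + fold_enrichment + summit-offset columns."""
    with open(path, "w") as fh:
        for p in cistrome:
            fh.write(
                f"{p.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                f"{p.id}\t{p.score:g}\t.\t{p.fold_enrichment:g}\t"
                f"{p.summit - p.interval.start}\n"
            )


def read_refflat(path: str | Path) -> list[GeneModel]:
    """Read a refFlat-style table (UCSC): one :class:`GeneModel` per
    transcript.  Columns: geneName, name, chrom, strand, txStart, txEnd,
    cdsStart, cdsEnd, exonCount, exonStarts, exonEnds.
    """
    models: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                gene, _name, chrom, strand = f[0], f[1], f[2], f[3]
                tx_start, tx_end = int(f[4]), int(f[5])
                starts = [int(x) for x in f[9].rstrip(",").split(",")]
                ends = [int(x) for x in f[10].rstrip(",").split(",")]
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"{path}:{lineno}: malformed refFlat line: {exc}"
                ) from exc
            exons = tuple(
                GenomicInterval(chrom, s, e) for s, e in zip(starts, ends)
            )
            tss = tx_start if strand == "+" else tx_end - 1
            models.append(GeneModel(gene, tss, strand, chrom, exons))
    return models


# ---------------------------------------------------------------------------
# Overlap algebra


@dataclass
class OverlapResult:
    """Result of overlapping two cistromes at >= 1 bp."""

    mapping: dict[str, list[Peak]]
    shared_a: int
    shared_b: int
    unique_a: int
    unique_b: int


def overlap_sets(a: CistromeSet, b: CistromeSet) -> OverlapResult:
    """Map each peak of *a* to the peaks of *b* sharing >= 1 bp with it.

    ``shared_a``/``unique_a`` count a-peaks with/without a b-overlap;
    ``shared_b``/``unique_b`` the converse.
    """
    trees_b = b.tree()
    mapping: dict[str, list[Peak]] = {}
    hit_b_ids: set[int] = set()
    for p in a:
        tree = trees_b.get(p.chrom)
        if tree is None:
            continue
        hits = tree.overlap(p.interval.start, p.interval.end)
        if hits:
            mapping[p.id] = sorted(
                (h.data for h in hits), key=lambda q: q.interval.start
            )
            hit_b_ids.update(id(h.data) for h in hits)
    shared_a = len(mapping)
    shared_b = len(hit_b_ids)
    return OverlapResult(
        mapping=mapping,
        shared_a=shared_a,
        shared_b=shared_b,
        unique_a=len(a) - shared_a,
        unique_b=len(b) - shared_b,
    )


# ---------------------------------------------------------------------------
# TSS association


@dataclass(frozen=True)
class PeakAssociation:
    """A peak associated with a gene, with its summit-to-TSS distance."""

    peak: Peak
    distance: int


def map_to_tss(
    cistrome: CistromeSet,
    genes: Sequence[GeneModel],
    max_dist: int = 25_000,
    use_summit: bool = True,
    known_chroms: set[str] | None = None,
) -> dict[str, list[PeakAssociation]]:
    """Associate peaks with genes whose TSS lies within *max_dist* bp.

    Distance is the absolute bp distance from the peak summit (or nearest
    peak edge when ``use_summit=False``) to the TSS; the boundary is
    inclusive (``distance <= max_dist``).  Multi-transcript genes use the
    nearest TSS.  Strand plays no role in the distance.
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be > 0")
    peak_chroms = {p.chrom for p in cistrome}
    if known_chroms is None:
        known_chroms = peak_chroms
    # per-chromosome sorted summit arrays for binary search
    by_chrom: dict[str, list[Peak]] = {}
    for p in cistrome:
        by_chrom.setdefault(p.chrom, []).append(p)
    anchors: dict[str, np.ndarray] = {}
    for chrom, plist in by_chrom.items():
        plist.sort(key=lambda p: p.summit)
        anchors[chrom] = np.array([p.summit for p in plist])

    out: dict[str, list[PeakAssociation]] = {}
    for g in genes:
        if g.chrom not in known_chroms:
            logger.warning("gene %s on unknown chromosome %s; skipped", g.gene, g.chrom)
            continue
        plist = by_chrom.get(g.chrom)
        if not plist:
            continue
        pos = anchors[g.chrom]
        lo = int(np.searchsorted(pos, g.tss - max_dist, side="left"))
        hi = int(np.searchsorted(pos, g.tss + max_dist, side="right"))
        for p in plist[lo:hi]:
            if use_summit:
                d = abs(p.summit - g.tss)
            else:
                d = min(
                    abs(p.interval.start - g.tss),
                    abs(p.interval.end - 1 - g.tss),
                )
                if p.interval.contains(g.tss):
                    d = 0
            if d <= max_dist:
                out.setdefault(g.gene, []).append(PeakAssociation(p, d))
    # a gene seen through several transcripts may list the same peak twice;
    # keep the nearest-TSS association per (gene, peak)
    for gene, assocs in out.items():
        best: dict[str, PeakAssociation] = {}
        for a in assocs:
            key = a.peak.id or f"{a.peak.chrom}:{a.peak.interval.start}"
            if key not in best or a.distance < best[key].distance:
                best[key] = a
        out[gene] = sorted(best.values(), key=lambda a: a.distance)
    return out


# ---------------------------------------------------------------------------
# Annotation classification


CATEGORIES = ("promoter", "exonic", "intronic", "intergenic")


@dataclass
class AnnotationResult:
    counts: dict[str, int]
    fractions: dict[str, float]
    background_fractions: dict[str, float]
    enrichment: dict[str, float | None]


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals.sort()
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _coverage(intervals: list[tuple[int, int]]) -> int:
    return sum(e - s for s, e in _merge(intervals))


def _promoter_window(g: GeneModel, window: tuple[int, int]) -> tuple[int, int]:
    """Strand-aware promoter window around the TSS.

    ``window=(-1000, 100)`` means 1000 bp upstream through 100 bp
    downstream of the TSS in the direction of transcription.
    """
    up, down = window
    if g.strand == "+":
        return (max(0, g.tss + up), g.tss + down + 1)
    return (max(0, g.tss - down), g.tss - up + 1)


def classify_annotation(
    cistrome: CistromeSet,
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    promoter_window: tuple[int, int] = (-1000, 100),
) -> AnnotationResult:
    """Classify each peak summit as promoter / exonic / intronic /
    intergenic (in that precedence) and compute fold over-representation
    of each category against its genomic background fraction.

    Background fractions are the genome-wide base-pair fractions of each
    category under the same precedence, computed from *chrom_sizes* and
    the gene models.  Enrichment = observed fraction / background
    fraction; ``None`` where the background fraction is zero.
    """
    proms: dict[str, list[tuple[int, int]]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    spans: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        if g.chrom not in chrom_sizes:
            continue
        proms.setdefault(g.chrom, []).append(_promoter_window(g, promoter_window))
        if g.exons:
            for e in g.exons:
                exons.setdefault(g.chrom, []).append((e.start, e.end))
        else:  # exonless model: the whole span counts as exonic
            exons.setdefault(g.chrom, []).append((g.tx_start, g.tx_end))
        spans.setdefault(g.chrom, []).append((g.tx_start, g.tx_end))

    prom_trees = {c: _merge(v) for c, v in proms.items()}
    exon_trees = {c: _merge(v) for c, v in exons.items()}
    span_trees = {c: _merge(v) for c, v in spans.items()}

    def _covered(merged: list[tuple[int, int]], pos: int) -> bool:
        import bisect
        i = bisect.bisect_right(merged, (pos, float("inf"))) - 1
        return i >= 0 and merged[i][0] <= pos < merged[i][1]

    counts = dict.fromkeys(CATEGORIES, 0)
    for p in cistrome:
        c, s = p.chrom, p.summit
        if _covered(prom_trees.get(c, []), s):
            counts["promoter"] += 1
        elif _covered(exon_trees.get(c, []), s):
            counts["exonic"] += 1
        elif _covered(span_trees.get(c, []), s):
            counts["intronic"] += 1
        else:
            counts["intergenic"] += 1

    n = len(cistrome)
    fractions = {k: (v / n if n else 0.0) for k, v in counts.items()}

    genome = sum(chrom_sizes.values())
    bg_bp = dict.fromkeys(CATEGORIES, 0)
    for chrom in chrom_sizes:
        pm = prom_trees.get(chrom, [])
        ex = exon_trees.get(chrom, [])
        sp = span_trees.get(chrom, [])
        p_bp = _coverage(pm)
        # exonic: exon bp not under a promoter; intronic: span bp not under
        # promoter or exon.  Computed by inclusion-exclusion on merged sets.
        pm_ex = _coverage(pm + ex)
        pm_ex_sp = _coverage(pm + ex + sp)
        e_bp = pm_ex - p_bp
        i_bp = pm_ex_sp - pm_ex
        bg_bp["promoter"] += p_bp
        bg_bp["exonic"] += e_bp
        bg_bp["intronic"] += i_bp
        bg_bp["intergenic"] += chrom_sizes[chrom] - p_bp - e_bp - i_bp
    background = {k: v / genome for k, v in bg_bp.items()}
    enrichment = {
        k: (fractions[k] / background[k] if background[k] > 0 else None)
        for k in CATEGORIES
    }
    return AnnotationResult(counts, fractions, background, enrichment)
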