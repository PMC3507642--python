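"""Tag-density tracks, robust per-site signal and signed fold changes.

The genome is divided into fixed-width bins (32 nt by default) and each
sequencing tag, extended in its 3' direction to the expected fragment
length, increments every bin it overlaps.  A per-site "signal" is then
the one-step Tukey biweight of the bin densities under the site, which
down-weights isolated outlier bins while equalling the plain mean on
well-behaved data.  Fold changes between conditions are reported on the
signed-ratio scale (+r for increases, -1/r for decreases, so |value| is
always >= 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import Peak

__all__ = [
    "TagTrack",
    "SiteSignal",
    "FoldChange",
    "build_tag_track",
    "tukey_biweight",
    "site_signal",
    "signed_fold_change",
    "dose_trend",
    "read_bedgraph",
    "write_bedgraph",
    "write_wiggle",
]

DEFAULT_BIN_SIZE = 32
DEFAULT_EXTENSION = 200  # assumed fragment length for 3' extension


@dataclass
class TagTrack:
    """Fixed-bin tag-density vectors, one per chromosome."""

    bin_size: int
    extension: int
    counts: dict[str, np.ndarray]
    total_tags: int = 0

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")

    def chrom_bins(self, chrom: str) -> np.ndarray:
        return self.counts[chrom]


@dataclass(frozen=True)
class SiteSignal:
    peak_id: str
    signal: float

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError("signal must be >= 0")


@dataclass(frozen=True)
class FoldChange:
    """Signed-ratio fold change; |value| >= 1 by construction."""

    peak_id: str
    value: float

    def __post_init__(self) -> None:
        if -1 < self.value < 1:
            raise ValueError(f"|fold change| must be >= 1, got {self.value}")


def build_tag_track(
    tag_positions: Iterable[tuple[str, int, str]],
    chrom_sizes: Mapping[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    extension: int = DEFAULT_EXTENSION,
) -> TagTrack:
    """Bin 3'-extended tags into fixed-width bins.

    Each tag is given as (chrom, 5'-end position, strand).  A + strand
    tag at position p covers [p, p+extension); a - strand tag covers
    (p-extension, p], i.e. [p-extension+1, p+1).  Every bin overlapping
    the extended tag is incremented by 1.  Tags whose 5' end lies outside
    the chromosome are rejected (counted, not raised).
    """
    counts = {
        c: np.zeros(int(np.ceil(size / bin_size)), dtype=np.int64)
        for c, size in chrom_sizes.items()
    }
    total = 0
    rejected = 0
    for chrom, pos, strand in tag_positions:
        size = chrom_sizes.get(chrom)
        if size is None or pos < 0 or pos >= size:
            rejected += 1
            continue
        if strand == "+":
            start, end = pos, min(pos + extension, size)
        else:
            start, end = max(0, pos - extension + 1), pos + 1
        b0 = start // bin_size
        b1 = (end - 1) // bin_size
        counts[chrom][b0 : b1 + 1] += 1
        total += 1
    track = TagTrack(bin_size=bin_size, extension=extension, counts=counts, total_tags=total)
    track.rejected = rejected  # type: ignore[attr-defined]
    return track


def tukey_biweight(values: Sequence[float], c: float = 5.0, eps: float = 1e-4) -> float:
    """One-step Tukey biweight location estimate.

    With m = median(x) and s = MAD(x) (median absolute deviation from
    the median, unscaled), each value gets a bisquare weight
    w_i = (1 - u_i^2)^2 for |u_i| < 1, else 0, where
    u_i = (x_i - m) / (c*s + eps).  The estimate is the weighted mean.
    When MAD = 0 only values equal to the median retain weight, so a
    lone outlier among constant values is ignored entirely.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    m = float(np.median(x))
    s = float(np.median(np.abs(x - m)))
    u = (x - m) / (c * s + eps)
    w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
    total = w.sum()
    if total == 0:  # unreachable: the median itself always has weight 1
        return m
    return float((w * x).sum() / total)


def site_signal(track: TagTrack, peak: Peak) -> SiteSignal:
    """Biweight-combined density of the bins overlapping the peak by >= 1 bp."""
    if peak.chrom not in track.counts:
        raise ValueError(f"chromosome {peak.chrom} absent from track")
    bs = track.bin_size
    b0 = peak.interval.start // bs
    b1 = (peak.interval.end - 1) // bs
    vec = track.counts[peak.chrom][b0 : b1 + 1]
    if vec.size == 0:
        raise ValueError(f"peak {peak.id} overlaps no bins")
    return SiteSignal(peak.id, tukey_biweight(vec))


def signed_fold_change(
    s_treated: float,
    s_reference: float,
    peak_id: str = "",
    pseudocount: float = 0.5,
) -> FoldChange:
    """Signed-ratio fold change of treated over reference signal.

    r = s_treated / s_reference; returns +r when r >= 1 and -1/r
    otherwise.  When either signal is 0 the *pseudocount* is added to
    both to keep the ratio finite; negative inputs are an error.
    """
    if s_treated < 0 or s_reference < 0:
        raise ValueError("signals must be non-negative")
    if s_treated == 0 or s_reference == 0:
        s_treated += pseudocount
        s_reference += pseudocount
    r = s_treated / s_reference
    return FoldChange(peak_id, r if r >= 1 else -1.0 / r)


@dataclass
class DoseTrend:
    moving_average: np.ndarray
    slope: float
    intercept: float


def dose_trend(
    ordered_fold_changes: Sequence[FoldChange | float],
    window: int = 100,
) -> DoseTrend:
    """Moving average of fold changes along descending site strength,
    plus a least-squares linear trend over the smoothed series.

    Input must already be sorted by descending site strength.  Output
    length is n - window + 1.
    """
    vals = np.array(
        [f.value if isinstance(f, FoldChange) else float(f) for f in ordered_fold_changes]
    )
    n = vals.size
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    kernel = np.ones(window) / window
    ma = np.convolve(vals, kernel, mode="valid")
    x = np.arange(ma.size)
    if ma.size > 1:
        slope, intercept = np.polyfit(x, ma, 1)
    else:
        slope, intercept = 0.0, float(ma[0])
    return DoseTrend(ma, float(slope), float(intercept))


# ---------------------------------------------------------------------------
# Track I/O


def write_bedgraph(track: TagTrack, path: str | Path) -> None:
    """Write non-zero bins as bedGraph (zero bins are implicit)."""
    bs = track.bin_size
    with open(path, "w") as fh:
        fh.write(f"# bin_size={bs} extension={track.extension} total_tags={track.total_tags}\n")
        for chrom in sorted(track.counts):
            vec = track.counts[chrom]
            nz = np.flatnonzero(vec)
            for i in nz:
                fh.write(f"{chrom}\t{i * bs}\t{(i + 1) * bs}\t{vec[i]}\n")


def read_bedgraph(
    path: str | Path,
    chrom_sizes: Mapping[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    extension: int = DEFAULT_EXTENSION,
) -> TagTrack:
    """Read a bedGraph whose intervals are aligned to *bin_size* bins."""
    counts = {
        c: np.zeros(int(np.ceil(size / bin_size)), dtype=np.int64)
        for c, size in chrom_sizes.items()
    }
    total = 0
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                if line.startswith("# bin_size="):
                    pass
                continue
            chrom, start, end, value = line.split("\t")
            start, end, value = int(start), int(end), int(float(value))
            if chrom not in counts:
                continue
            b0, b1 = start // bin_size, (end - 1) // bin_size
            counts[chrom][b0 : b1 + 1] = value
            total += value
    return TagTrack(bin_size=bin_size, extension=extension, counts=counts, total_tags=total)


def write_wiggle(track: TagTrack, path: str | Path) -> None:
    """Write the track as fixedStep wiggle (step = span = bin_size)."""
    bs = track.bin_size
    with open(path, "w") as fh:
        for chrom in sorted(track.counts):
            fh.write(f"fixedStep chrom={chrom} start=1 step={bs} span={bs}\n")
            fh.write("\n".join(str(v) for v in track.counts[chrom]))
            fh.write("\n")
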