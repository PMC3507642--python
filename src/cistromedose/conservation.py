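"""Summit-anchored evolutionary-conservation profiling.

Conservation is read from a track of pre-computed conserved elements
(phastCons-style: non-overlapping intervals, each carrying a score in
[0, 1]).  The conservation value at a position is the score of the
covering element, or zero outside all elements.  Profiles sample that
value on a fixed offset grid around each peak summit; the association
between binding mode (activation vs repression) and binary
conserved/non-conserved status of the summit is tested with a two-tailed
Fisher exact test.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .intervals import CistromeSet, GenomicInterval

__all__ = [
    "ConservedElement",
    "ConservationTrack",
    "ConservationProfile",
    "read_conserved_bed",
    "write_conserved_bed",
    "sample_conservation",
    "mean_profile",
    "conservation_mode_association",
    "write_profile_tsv",
]

DEFAULT_STEP = 100
DEFAULT_SPAN = 10_000


@dataclass(frozen=True)
class ConservedElement:
    interval: GenomicInterval
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"conservation score must be in [0,1], got {self.score}")


class ConservationTrack:
    """Per-chromosome sorted, non-overlapping conserved elements with
    O(log n) point lookup."""

    def __init__(self, elements: Iterable[ConservedElement]):
        by_chrom: dict[str, list[ConservedElement]] = {}
        for el in elements:
            by_chrom.setdefault(el.interval.chrom, []).append(el)
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        self._scores: dict[str, list[float]] = {}
        self.n_elements = 0
        for chrom, els in by_chrom.items():
            els.sort(key=lambda e: e.interval.start)
            for prev, cur in zip(els, els[1:]):
                if cur.interval.start < prev.interval.end:
                    raise ValueError(
                        f"overlapping conserved elements on {chrom} at "
                        f"{cur.interval.start}"
                    )
            self._starts[chrom] = [e.interval.start for e in els]
            self._ends[chrom] = [e.interval.end for e in els]
            self._scores[chrom] = [e.score for e in els]
            self.n_elements += len(els)

    def score_at(self, chrom: str, pos: int) -> float:
        """phastCons score of the element covering *pos*, else 0."""
        starts = self._starts.get(chrom)
        if not starts:
            return 0.0
        i = bisect.bisect_right(starts, pos) - 1
        if i >= 0 and pos < self._ends[chrom][i]:
            return self._scores[chrom][i]
        return 0.0

    def covers(self, chrom: str, pos: int) -> bool:
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect.bisect_right(starts, pos) - 1
        return i >= 0 and pos < self._ends[chrom][i]


@dataclass
class ConservationProfile:
    """Mean conservation on an offset grid centred at the summit."""

    offsets: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.offsets.shape != self.values.shape:
            raise ValueError("offsets and values must align")


def read_conserved_bed(path: str | Path) -> ConservationTrack:
    """Read a BED5 conserved-elements file.  Scores > 1 are assumed to
    follow the UCSC 0-1000 convention and are divided by 1000."""
    elements: list[ConservedElement] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                score = float(f[4]) if len(f) > 4 else 0.0
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED5 line: {exc}") from exc
            if score > 1.0:
                score /= 1000.0
            elements.append(ConservedElement(GenomicInterval(chrom, start, end), score))
    return ConservationTrack(elements)


def write_conserved_bed(elements: Iterable[ConservedElement], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, el in enumerate(elements):
            fh.write(
                f"{el.interval.chrom}\t{el.interval.start}\t{el.interval.end}"
                f"\tcons{i}\t{el.score * 1000:.0f}\n"
            )


def _offset_grid(step: int, span: int) -> np.ndarray:
    return np.arange(-span, span + step, step)


def sample_conservation(
    track: ConservationTrack,
    chrom: str,
    summit: int,
    step: int = DEFAULT_STEP,
    span: int = DEFAULT_SPAN,
    chrom_size: int | None = None,
) -> np.ndarray:
    """Conservation score sampled every *step* bp from the summit out to
    *span* bp on both sides (2*span/step + 1 samples).  Positions beyond
    the chromosome ends sample as 0."""
    if summit < 0:
        raise ValueError("summit must be >= 0")
    if chrom_size is not None and summit >= chrom_size:
        raise ValueError(f"summit {summit} beyond chromosome size {chrom_size}")
    offsets = _offset_grid(step, span)
    return np.array(
        [track.score_at(chrom, summit + int(o)) if summit + o >= 0 else 0.0 for o in offsets]
    )


def mean_profile(
    cistrome: CistromeSet,
    track: ConservationTrack,
    step: int = DEFAULT_STEP,
    span: int = DEFAULT_SPAN,
) -> ConservationProfile:
    """Pointwise mean of per-peak summit-anchored conservation samples."""
    if len(cistrome) == 0:
        raise ValueError("cannot profile an empty cistrome")
    offsets = _offset_grid(step, span)
    acc = np.zeros_like(offsets, dtype=float)
    for p in cistrome:
        acc += sample_conservation(track, p.chrom, p.summit, step, span)
    return ConservationProfile(offsets, acc / len(cistrome))


@dataclass(frozen=True)
class ModeAssociation:
    table: tuple[tuple[int, int], tuple[int, int]]
    p_value: float
    conserved_fraction_a: float
    conserved_fraction_b: float


def conservation_mode_association(
    peaks_a: CistromeSet,
    peaks_b: CistromeSet,
    track: ConservationTrack,
) -> ModeAssociation:
    """Two-tailed Fisher exact test of conserved/non-conserved summit
    status between two peak groups (e.g. sites near activation vs
    repression targets)."""
    if len(peaks_a) == 0 or len(peaks_b) == 0:
        raise ValueError("both peak groups must be non-empty")
    cons_a = sum(track.covers(p.chrom, p.summit) for p in peaks_a)
    cons_b = sum(track.covers(p.chrom, p.summit) for p in peaks_b)
    table = (
        (cons_a, len(peaks_a) - cons_a),
        (cons_b, len(peaks_b) - cons_b),
    )
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return ModeAssociation(
        table=table,
        p_value=float(p),
        conserved_fraction_a=cons_a / len(peaks_a),
        conserved_fraction_b=cons_b / len(peaks_b),
    )


def write_profile_tsv(profile: ConservationProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("offset\tmean_score\n")
        for o, v in zip(profile.offsets, profile.values):
            fh.write(f"{int(o)}\t{v:.6f}\n")
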