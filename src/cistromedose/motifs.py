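"""PWM scanning, palindrome detection, matched-background specificity
Z-scores, element-pair spacing and motif-regulation-mode association.

Scanning is a plain log-odds scan: each window of sequence is scored as
sum over columns of log2(p_column[base] / background[base]); windows
containing N are skipped; the reverse strand is scored on the reverse
complement.  Specificity of a motif for a bound-sequence set is a
Z-score against 100 random groups of sequences matched in number,
length and chromosome of origin, following the "distance from the
population mean in units of the population standard deviation"
convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .cistrome import RankSumResult, compare_strength_groups

logger = logging.getLogger(__name__)

__all__ = [
    "PWM",
    "MotifHit",
    "SpacingHistogram",
    "scan_pwm",
    "scan_sequences",
    "is_palindromic",
    "motif_zscore",
    "pair_spacing",
    "motif_mode_association",
    "score_strength_association",
    "read_fasta",
    "write_fasta",
    "read_meme_pwm",
    "write_meme_pwm",
    "extract_summit_sequences",
]

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_CODE["N"] = 4
DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_REL_THRESHOLD = 0.6  # fraction of the maximal log-odds score


class PWM:
    """A position weight matrix over A,C,G,T.

    ``probs`` is a 4 x width column-stochastic matrix (rows in ACGT
    order).  A pseudocount is added per cell and columns renormalised at
    construction, so log-odds scores are always finite.
    """

    def __init__(
        self,
        probs: np.ndarray,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        background: Sequence[float] | None = None,
        name: str = "",
    ):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[0] != 4:
            raise ValueError("probs must be a 4 x width matrix (rows A,C,G,T)")
        if np.any(probs < 0):
            raise ValueError("probabilities must be non-negative")
        probs = probs + pseudocount
        self.probs = probs / probs.sum(axis=0, keepdims=True)
        self.pseudocount = pseudocount
        self.background = np.asarray(
            background if background is not None else [0.25] * 4, dtype=float
        )
        self.background = self.background / self.background.sum()
        self.name = name

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    def log_odds(self, background: Sequence[float] | None = None) -> np.ndarray:
        bg = np.asarray(background, dtype=float) if background is not None else self.background
        bg = bg / bg.sum()
        return np.log2(self.probs / bg[:, None])

    def max_score(self, background: Sequence[float] | None = None) -> float:
        return float(self.log_odds(background).max(axis=0).sum())

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=0))

    def reverse_complement(self) -> "PWM":
        rc = PWM.__new__(PWM)
        rc.probs = self.probs[::-1, ::-1].copy()
        rc.pseudocount = self.pseudocount
        rc.background = self.background.copy()
        rc.name = self.name + "_rc" if self.name else ""
        return rc

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        background: Sequence[float] | None = None,
        name: str = "",
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        return cls(counts / counts.sum(axis=0, keepdims=True), pseudocount, background, name)


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    position: int  # 0-based offset of the match start on the forward strand
    strand: str
    score: float  # log-odds, bits
    width: int

    @property
    def midpoint(self) -> float:
        return self.position + (self.width - 1) / 2.0


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, 4) for c in seq.upper()], dtype=np.int8)


def _revcomp(seq: str) -> str:
    return seq.upper().translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _window_scores(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Log-odds score of every window; NaN where the window contains N."""
    w = lo.shape[1]
    if codes.size < w:
        return np.empty(0)
    windows = sliding_window_view(codes, w)
    valid = ~(windows == 4).any(axis=-1)
    safe = np.where(windows == 4, 0, windows)
    scores = lo[safe, np.arange(w)].sum(axis=-1)
    return np.where(valid, scores, np.nan)


def resolve_threshold(pwm: PWM, threshold: float | None, background=None) -> float:
    """Default threshold: 60% of the maximal achievable log-odds score."""
    if threshold is not None:
        return threshold
    return DEFAULT_REL_THRESHOLD * pwm.max_score(background)


def scan_pwm(
    sequence: str,
    pwm: PWM,
    threshold: float | None = None,
    seq_id: str = "",
    background: Sequence[float] | None = None,
) -> list[MotifHit]:
    """Scan both strands of *sequence* for matches scoring >= threshold.

    Reverse-strand windows are scored on the reverse complement; their
    reported position is the match start on the forward strand.  Windows
    containing N are skipped.  A sequence shorter than the motif yields
    no hits.
    """
    thr = resolve_threshold(pwm, threshold, background)
    lo = pwm.log_odds(background)
    w = pwm.width
    hits: list[MotifHit] = []
    codes = _encode(sequence)
    fwd = _window_scores(codes, lo)
    for pos in np.flatnonzero(fwd >= thr):
        hits.append(MotifHit(seq_id, int(pos), "+", float(fwd[pos]), w))
    rc_codes = _encode(_revcomp(sequence))
    rev = _window_scores(rc_codes, lo)
    n = len(sequence)
    for pos in np.flatnonzero(rev >= thr):
        hits.append(MotifHit(seq_id, int(n - w - pos), "-", float(rev[pos]), w))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def scan_sequences(
    sequences: Mapping[str, str],
    pwm: PWM,
    threshold: float | None = None,
    background: Sequence[float] | None = None,
) -> dict[str, list[MotifHit]]:
    """Scan a collection of sequences; returns hits per sequence id."""
    return {
        sid: scan_pwm(seq, pwm, threshold, seq_id=sid, background=background)
        for sid, seq in sequences.items()
    }


def _batch_has_hit(seqs: list[str], lo: np.ndarray, thr: float) -> np.ndarray:
    """Fast path for equal-length sequences: boolean per-sequence
    'contains at least one hit on either strand'."""
    n = len(seqs)
    length = len(seqs[0])
    codes = np.empty((n, length), dtype=np.int8)
    for i, s in enumerate(seqs):
        codes[i] = _encode(s)
    rc_codes = np.empty_like(codes)
    comp = np.array([3, 2, 1, 0, 4], dtype=np.int8)
    rc_codes[:] = comp[codes[:, ::-1]]
    w = lo.shape[1]
    if length < w:
        return np.zeros(n, dtype=bool)
    out = np.zeros(n, dtype=bool)
    for mat in (codes, rc_codes):
        windows = sliding_window_view(mat, w, axis=1)
        valid = ~(windows == 4).any(axis=-1)
        safe = np.where(windows == 4, 0, windows)
        scores = lo[safe, np.arange(w)].sum(axis=-1)
        out |= ((scores >= thr) & valid).any(axis=1)
    return out


def is_palindromic(pwm: PWM, tol: float = 1e-6) -> bool:
    """True iff the matrix equals its reverse complement elementwise
    within *tol* — the signature of a motif bound by a homodimer."""
    return bool(np.allclose(pwm.probs, pwm.probs[::-1, ::-1], atol=tol))


@dataclass
class ZScoreResult:
    z: float
    bound_count: int
    random_mean: float
    random_sd: float
    infinite: bool = False


def motif_zscore(
    bound_seqs: Mapping[str, tuple[str, str]] | Mapping[str, str],
    pwm: PWM,
    genome: Mapping[str, str],
    threshold: float | None = None,
    background_groups: int = 100,
    seed: int = 0,
    background: Sequence[float] | None = None,
) -> ZScoreResult:
    """Specificity Z-score of a motif for a bound-sequence set.

    *bound_seqs* maps sequence id to either a plain sequence (sampled
    uniformly over genome chromosomes) or a (chrom, sequence) pair, in
    which case each random group draws a same-length window from the
    same chromosome — matching number, length and chromosome of origin.
    The statistic counted is the number of sequences containing at least
    one match.  Z = (bound - mean_random) / sd_random; if the random
    counts are constant the Z-score is flagged infinite.
    """
    items = list(bound_seqs.items())
    if not items:
        raise ValueError("no bound sequences")
    pairs: list[tuple[str | None, str]] = []
    for _, v in items:
        if isinstance(v, tuple):
            pairs.append((v[0], v[1]))
        else:
            pairs.append((None, v))
    thr = resolve_threshold(pwm, threshold, background)
    lo = pwm.log_odds(background)

    lengths = {len(s) for _, s in pairs}
    if len(lengths) == 1:
        bound_count = int(_batch_has_hit([s for _, s in pairs], lo, thr).sum())
    else:
        bound_count = sum(
            bool(scan_pwm(s, pwm, thr)) for _, s in pairs
        )

    rng = np.random.default_rng(seed)
    chrom_names = sorted(genome)
    counts = np.empty(background_groups)
    for g in range(background_groups):
        group: list[str] = []
        for chrom, seq in pairs:
            c = chrom if chrom in genome else chrom_names[rng.integers(len(chrom_names))]
            src = genome[c]
            L = len(seq)
            if len(src) <= L:
                start = 0
            else:
                start = int(rng.integers(0, len(src) - L))
            group.append(src[start : start + L])
        if len({len(s) for s in group}) == 1:
            counts[g] = _batch_has_hit(group, lo, thr).sum()
        else:
            counts[g] = sum(bool(scan_pwm(s, pwm, thr)) for s in group)
    mean, sd = float(counts.mean()), float(counts.std(ddof=0))
    if sd == 0:
        logger.warning("random-group counts constant; Z-score infinite")
        z = math.inf if bound_count > mean else (-math.inf if bound_count < mean else 0.0)
        return ZScoreResult(z, bound_count, mean, sd, infinite=True)
    return ZScoreResult((bound_count - mean) / sd, bound_count, mean, sd)


@dataclass
class SpacingHistogram:
    """Counts of middle-to-middle distances between co-occurring motif
    pairs, over a closed bp range (10-50 by default)."""

    distances: np.ndarray
    counts: np.ndarray

    @property
    def mode(self) -> int | None:
        if self.counts.sum() == 0:
            return None
        return int(self.distances[int(self.counts.argmax())])


def pair_spacing(
    hits_a: Iterable[MotifHit],
    hits_b: Iterable[MotifHit],
    lo: int = 10,
    hi: int = 50,
) -> SpacingHistogram:
    """Histogram of |mid_A - mid_B| (rounded to nearest bp) for pairs of
    hits on the same sequence, restricted to [lo, hi] bp."""
    by_seq_a: dict[str, list[MotifHit]] = {}
    for h in hits_a:
        by_seq_a.setdefault(h.seq_id, []).append(h)
    distances = np.arange(lo, hi + 1)
    counts = np.zeros(distances.size, dtype=int)
    for h in hits_b:
        for a in by_seq_a.get(h.seq_id, []):
            d = int(round(abs(a.midpoint - h.midpoint)))
            if lo <= d <= hi:
                counts[d - lo] += 1
    return SpacingHistogram(distances, counts)


@dataclass(frozen=True)
class ModeAssociationResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    p_value: float


def motif_mode_association(
    presence_by_site: Mapping[str, bool],
    mode_by_site: Mapping[str, str],
) -> ModeAssociationResult:
    """Two-tailed Fisher exact test of motif presence against regulation
    mode (activation vs repression) across binding sites."""
    modes = set(mode_by_site.values())
    if modes - {"activation", "repression"}:
        raise ValueError(f"unknown modes: {modes - {'activation', 'repression'}}")
    if modes != {"activation", "repression"}:
        raise ValueError("both regulation modes must be represented")
    cells = {("activation", True): 0, ("activation", False): 0,
             ("repression", True): 0, ("repression", False): 0}
    for site, mode in mode_by_site.items():
        cells[(mode, bool(presence_by_site.get(site, False)))] += 1
    table = (
        (cells[("activation", True)], cells[("activation", False)]),
        (cells[("repression", True)], cells[("repression", False)]),
    )
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return ModeAssociationResult(table, float(p))


def score_strength_association(
    scores_with_motif: Sequence[float],
    scores_without: Sequence[float],
) -> RankSumResult:
    """Rank-sum comparison of binding scores of motif-containing vs
    motif-lacking sites (delegates to the cistrome comparison)."""
    return compare_strength_groups(scores_with_motif, scores_without)


# ---------------------------------------------------------------------------
# I/O helpers


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in sequences.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_meme_pwm(path: str | Path) -> PWM:
    """Read the first motif from a MEME minimal-format text file."""
    probs_rows: list[list[float]] = []
    name = ""
    bg = None
    in_matrix = False
    with open(path) as fh:
        lines = iter(fh)
        for line in lines:
            s = line.strip()
            if s.startswith("MOTIF"):
                name = s.split()[1] if len(s.split()) > 1 else ""
            elif s.startswith("Background letter frequencies"):
                freq_line = next(lines).split()
                bg = [float(freq_line[i]) for i in (1, 3, 5, 7)]
            elif s.startswith("letter-probability matrix"):
                in_matrix = True
            elif in_matrix:
                if not s:
                    break
                parts = s.split()
                if len(parts) != 4:
                    break
                probs_rows.append([float(x) for x in parts])
    if not probs_rows:
        raise ValueError(f"no letter-probability matrix found in {path}")
    probs = np.array(probs_rows).T  # file rows are positions; we store 4 x w
    # file probabilities are taken as-is; regularize only if zeros present
    pc = 0.0 if (probs > 0).all() else DEFAULT_PSEUDOCOUNT
    return PWM(probs, pseudocount=pc, background=bg, name=name)


def write_meme_pwm(pwm: PWM, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            "A {0:.5f} C {1:.5f} G {2:.5f} T {3:.5f}\n\n".format(*pwm.background)
        )
        fh.write(f"MOTIF {pwm.name or 'motif1'}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {pwm.width} nsites= 100 E= 0\n"
        )
        for col in pwm.probs.T:
            fh.write(" ".join(f"{v:.6f}" for v in col) + "\n")


def extract_summit_sequences(
    genome: Mapping[str, str],
    cistrome,
    max_len: int = 500,
    top_n: int = 2500,
) -> dict[str, str]:
    """Summit-centred sequences for ab initio motif discovery.

    Sites longer than *max_len* are trimmed to *max_len* bp centred on
    the summit; only the *top_n* strongest sites (by score, ties by fold
    enrichment) are returned.  Feeds an external discovery tool; the
    discovery itself is out of scope here.
    """
    from .cistrome import sort_by_strength

    out: dict[str, str] = {}
    for p in sort_by_strength(cistrome)[:top_n]:
        chrom_seq = genome.get(p.chrom)
        if chrom_seq is None:
            continue
        start, end = p.interval.start, p.interval.end
        if end - start > max_len:
            start = max(0, p.summit - max_len // 2)
            end = start + max_len
        out[p.id or f"{p.chrom}:{start}-{end}"] = chrom_seq[start:end]
    return out
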