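"""High-confidence peak filtering against swapped-channel negatives,
cistrome comparison statistics, and the % impact dose metric.

"Negative" peaks — called after swapping the ChIP and control channels —
have no biological meaning and serve as a yardstick for technical noise:
a peak is high-confidence when its caller score and fold enrichment both
exceed every negative peak's.  The % impact of an antagonist dose is the
fraction of differentially occupied sites (sites in the maximal cistrome
with no counterpart in the minimal one) that are lost in the treated
cistrome.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .intervals import CistromeSet, Peak, overlap_sets

logger = logging.getLogger(__name__)

__all__ = [
    "FilterThresholds",
    "ImpactResult",
    "auto_thresholds",
    "filter_high_confidence",
    "percent_impact",
    "compare_strength_groups",
    "overlap_enrichment",
    "sort_by_strength",
]

DEFAULT_SCORE_CUT = 500.0
DEFAULT_FE_CUT = 20.0


@dataclass(frozen=True)
class FilterThresholds:
    """Joint score and fold-enrichment cutoffs (AND semantics)."""

    score_cut: float = DEFAULT_SCORE_CUT
    fe_cut: float = DEFAULT_FE_CUT

    def __post_init__(self) -> None:
        if self.score_cut < 0 or self.fe_cut < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass(frozen=True)
class ImpactResult:
    differential_sites: int
    lost_in_treated: int

    def __post_init__(self) -> None:
        if self.lost_in_treated > self.differential_sites:
            raise ValueError("lost sites cannot exceed differential sites")

    @property
    def percent_impact(self) -> float:
        return 100.0 * self.lost_in_treated / self.differential_sites


def auto_thresholds(negative: CistromeSet, round_to: float = 10.0) -> FilterThresholds:
    """Smallest round cutoffs excluding every negative peak.

    Each cutoff is the smallest multiple of *round_to* (1.0 for fold
    enrichment by default would be too coarse; we round fold enrichment
    to whole units) strictly greater than the corresponding maximum over
    the negative set.
    """
    if len(negative) == 0:
        raise ValueError("cannot calibrate thresholds from an empty negative set")
    max_score = max(p.score for p in negative)
    max_fe = max(p.fold_enrichment for p in negative)
    score_cut = (math.floor(max_score / round_to) + 1) * round_to
    fe_cut = math.floor(max_fe) + 1.0
    return FilterThresholds(score_cut, fe_cut)


def filter_high_confidence(
    positive: CistromeSet,
    negative: CistromeSet | None = None,
    thresholds: FilterThresholds | str = FilterThresholds(),
) -> CistromeSet:
    """Retain peaks with score >= score_cut AND fold enrichment >= fe_cut.

    With ``thresholds="auto"`` the cutoffs are calibrated from the
    negative (swapped-channel) set via :func:`auto_thresholds`.
    """
    if isinstance(thresholds, str):
        if thresholds != "auto":
            raise ValueError(f"unknown thresholds mode {thresholds!r}")
        if negative is None:
            raise ValueError("auto thresholds require a negative set")
        thresholds = auto_thresholds(negative)
    kept = [
        p
        for p in positive
        if p.score >= thresholds.score_cut and p.fold_enrichment >= thresholds.fe_cut
    ]
    return CistromeSet(f"{positive.label}|hc", kept)


def percent_impact(
    max_set: CistromeSet,
    min_set: CistromeSet,
    treated: CistromeSet,
) -> ImpactResult:
    """% impact of a treatment on the differentially occupied sites.

    Differential sites are max_set peaks with no >= 1 bp overlap in
    min_set; a differential site is "lost" when it has no >= 1 bp
    overlap in the treated cistrome.  treated == max_set gives 0%,
    treated == min_set gives 100%.  Matching is by overlap, not peak id,
    since peak boundaries shift between independent calls.
    """
    ov_min = overlap_sets(max_set, min_set)
    if ov_min.shared_b < len(min_set):
        logger.warning(
            "minimal cistrome not a subset of maximal: %d/%d min peaks unmatched",
            len(min_set) - ov_min.shared_b,
            len(min_set),
        )
    differential = [p for p in max_set if p.id not in ov_min.mapping]
    if not differential:
        raise ValueError("no differentially occupied sites; % impact undefined")
    diff_set = CistromeSet("differential", differential)
    ov_treated = overlap_sets(diff_set, treated)
    lost = len(differential) - ov_treated.shared_a
    return ImpactResult(differential_sites=len(differential), lost_in_treated=lost)


@dataclass(frozen=True)
class RankSumResult:
    statistic: float
    p_value: float
    median_a: float
    median_b: float


def compare_strength_groups(
    scores_a: list[float] | np.ndarray,
    scores_b: list[float] | np.ndarray,
) -> RankSumResult:
    """Two-sided Mann-Whitney U comparison of binding-score groups."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    if np.all(a == a[0]) and np.all(b == a[0]):
        # fully tied across both groups: no evidence either way
        return RankSumResult(a.size * b.size / 2.0, 1.0, med_a, med_b)
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return RankSumResult(float(u), float(min(p, 1.0)), med_a, med_b)


def overlap_enrichment(
    universe_size: int,
    set_a: int,
    set_b: int,
    shared: int,
) -> float:
    """Upper hypergeometric tail P(X >= shared) for the overlap of two
    sets of sizes |A| and |B| drawn from a universe of N genes/sites."""
    if not (0 <= set_a <= universe_size and 0 <= set_b <= universe_size):
        raise ValueError("set sizes must lie within the universe")
    if shared < 0 or shared > min(set_a, set_b):
        raise ValueError("shared count impossible for the given set sizes")
    if shared < set_a + set_b - universe_size:
        raise ValueError("shared count below the forced minimum overlap")
    return float(stats.hypergeom.sf(shared - 1, universe_size, set_a, set_b))


def sort_by_strength(cistrome: CistromeSet) -> list[Peak]:
    """Sort peaks by descending score, ties by descending fold
    enrichment, remaining ties by genomic coordinate (documented
    tie-break beyond the two keys)."""
    return sorted(
        cistrome,
        key=lambda p: (-p.score, -p.fold_enrichment, p.chrom, p.interval.start),
    )
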