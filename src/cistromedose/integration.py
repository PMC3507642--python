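"""Cistrome-transcriptome integration.

Consumes per-probe differential-expression tables (fold change on the
signed-ratio scale, d-score, q-value), filters them to significantly
regulated genes, correlates treatment profiles, and crosses
drug-impacted binding with expression direction to classify direct
activation targets (binding impacted, expression down under antagonist)
and direct repression targets (binding impacted, expression up).  Also
implements the qPCR concordance arithmetic used to validate peak-caller
scores against bench enrichment measurements.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cistrome import overlap_enrichment
from .intervals import GenomicInterval, PeakAssociation

__all__ = [
    "DETable",
    "DirectTarget",
    "QPCRRecord",
    "de_significant",
    "profile_concordance",
    "classify_direct_targets",
    "qpcr_concordance",
    "qpcr_fold_filter",
    "load_table1",
]

DE_COLUMNS = ["probe_id", "gene", "fold_change", "d_score", "q_value"]


class DETable:
    """Per-probe differential-expression records.

    Fold changes are on the signed-ratio scale (+2 means doubled, -2
    halved; |FC| >= 1), matching common microarray significance-analysis
    output.  q_value is the per-probe FDR.
    """

    def __init__(self, df: pd.DataFrame):
        missing = set(DE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"DE table missing columns: {sorted(missing)}")
        if df.empty:
            raise ValueError("DE table is empty")
        if ((df["q_value"] < 0) | (df["q_value"] > 1)).any():
            raise ValueError("q_value outside [0,1]")
        if (df["fold_change"] == 0).any():
            raise ValueError("fold_change must be non-zero (signed-ratio scale)")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DETable":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class DirectTarget:
    """A gene classified as a direct activation or repression target.

    ``mode="activation"`` means the gene's expression is significantly
    down-regulated when its associated binding is lost under antagonist
    (the factor was activating it); ``"repression"`` the converse.
    """

    gene: str
    mode: str
    peaks: tuple[str, ...]
    tss_distance: int

    def __post_init__(self) -> None:
        if self.mode not in ("activation", "repression"):
            raise ValueError(f"mode must be activation/repression, got {self.mode!r}")


@dataclass(frozen=True)
class QPCRRecord:
    region: GenomicInterval
    fold_enrichment_qpcr: float
    binding_score: float | None = None

    def __post_init__(self) -> None:
        if self.fold_enrichment_qpcr <= 0:
            raise ValueError("qPCR fold enrichment must be > 0")


def de_significant(
    table: DETable,
    fdr: float = 0.05,
    fc_cut: float = 1.5,
) -> tuple[set[str], set[str]]:
    """Significantly up- and down-regulated gene sets.

    A gene is included when at least one of its probes passes both cuts
    (q < fdr and |FC| > fc_cut).  Genes whose passing probes disagree in
    direction are excluded from both sets.
    """
    df = table.df
    passing = df[(df["q_value"] < fdr) & (df["fold_change"].abs() > fc_cut)]
    up, down = set(), set()
    for gene, grp in passing.groupby("gene"):
        has_up = (grp["fold_change"] > 0).any()
        has_down = (grp["fold_change"] < 0).any()
        if has_up and has_down:
            continue  # discordant probes: drop the gene
        (up if has_up else down).add(str(gene))
    return up, down


@dataclass
class ConcordanceResult:
    r_fold_change: float
    p_fold_change: float
    r_d_score: float
    p_d_score: float
    n_probes: int
    up_overlap_p: float
    down_overlap_p: float


def profile_concordance(
    table_a: DETable,
    table_b: DETable,
    fdr: float = 0.05,
    fc_cut: float = 1.5,
) -> ConcordanceResult:
    """Genome-wide concordance of two treatment profiles.

    Pearson correlation of fold changes and of d-scores over the probes
    shared by both tables, plus hypergeometric enrichment of the overlap
    between the two treatments' significantly up- (and down-) regulated
    gene sets, with the shared genes as the universe.
    """
    merged = table_a.df.merge(table_b.df, on="probe_id", suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise ValueError("need >= 3 shared probes for correlation")
    r_fc, p_fc = stats.pearsonr(merged["fold_change_a"], merged["fold_change_b"])
    r_d, p_d = stats.pearsonr(merged["d_score_a"], merged["d_score_b"])

    up_a, down_a = de_significant(table_a, fdr, fc_cut)
    up_b, down_b = de_significant(table_b, fdr, fc_cut)
    universe = set(table_a.df["gene"]) & set(table_b.df["gene"])
    n = len(universe)

    def _tail(sa: set[str], sb: set[str]) -> float:
        a, b = sa & universe, sb & universe
        if not a or not b:
            return 1.0
        return overlap_enrichment(n, len(a), len(b), len(a & b))

    return ConcordanceResult(
        float(r_fc), float(p_fc), float(r_d), float(p_d), len(merged),
        _tail(up_a, up_b), _tail(down_a, down_b),
    )


def classify_direct_targets(
    impacted_genes: Mapping[str, Sequence[PeakAssociation]],
    up_genes: set[str],
    down_genes: set[str],
) -> list[DirectTarget]:
    """Cross impacted binding with expression direction.

    Activation targets: genes with impacted binding near the TSS whose
    expression goes down under antagonist.  Repression targets: impacted
    binding, expression up.  The up and down sets must be disjoint
    (guaranteed by :func:`de_significant`).
    """
    both = up_genes & down_genes
    if both:
        raise ValueError(f"genes in both up and down sets: {sorted(both)[:5]}")
    targets: list[DirectTarget] = []
    for gene, assocs in impacted_genes.items():
        if gene in down_genes:
            mode = "activation"
        elif gene in up_genes:
            mode = "repression"
        else:
            continue
        peak_ids = tuple(a.peak.id for a in assocs)
        dist = min(a.distance for a in assocs)
        targets.append(DirectTarget(gene, mode, peak_ids, dist))
    targets.sort(key=lambda t: t.gene)
    return targets


@dataclass
class QPCRConcordance:
    r: float
    p_two_sided: float
    p_one_sided: float
    n: int


def qpcr_concordance(
    records: Iterable[QPCRRecord],
    log_scale: bool = False,
) -> QPCRConcordance:
    """Pearson correlation of peak-caller binding scores against qPCR
    fold enrichment, over records carrying both values.

    Raw (untransformed) values by default; ``log_scale=True`` correlates
    natural logs instead.  Both the two-sided p and the one-sided
    (positive-association) tail, which is half of it, are reported.
    """
    pairs = [
        (r.binding_score, r.fold_enrichment_qpcr)
        for r in records
        if r.binding_score is not None
    ]
    if len(pairs) < 3:
        raise ValueError("need >= 3 records with both binding score and qPCR value")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if log_scale:
        x, y = np.log(x), np.log(y)
    r, p = stats.pearsonr(x, y)
    p_one = p / 2 if r > 0 else 1 - p / 2
    return QPCRConcordance(float(r), float(p), float(p_one), len(pairs))


def qpcr_fold_filter(records: Iterable[QPCRRecord], threshold: float = 3.0) -> int:
    """Count records whose qPCR fold enrichment exceeds *threshold*."""
    return sum(r.fold_enrichment_qpcr > threshold for r in records)


def load_table1() -> list[QPCRRecord]:
    """The packaged qPCR validation table: twelve binding sites with
    qPCR fold enrichment over a negative control region, eleven of which
    also carry a peak-caller binding score."""
    ref = importlib.resources.files("cistromedose").joinpath("data/table1.tsv")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    records = []
    for row in df.itertuples(index=False):
        score = None if pd.isna(row.binding_score) else float(row.binding_score)
        records.append(
            QPCRRecord(
                region=GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
                fold_enrichment_qpcr=float(row.qpcr_fold_enrichment),
                binding_score=score,
            )
        )
    return records
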