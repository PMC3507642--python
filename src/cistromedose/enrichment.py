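"""Gene-signature enrichment of target lists.

Target gene sets (e.g. direct activation or repression targets) are
tested against curated signature collections with the cumulative
hypergeometric distribution, corrected for multiple testing with Storey
q-values, and exported as a node/edge network of significant signatures
for graph viewers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cistrome import overlap_enrichment

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureSet",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "signature_enrichment",
    "qvalues",
    "export_enrichment_network",
]


@dataclass(frozen=True)
class SignatureSet:
    name: str
    genes: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has no genes")


@dataclass
class EnrichmentResult:
    signature: str
    overlap: int
    signature_size: int  # within the universe
    expected: float
    p: float
    q: float = float("nan")


def read_gmt(path: str | Path) -> list[SignatureSet]:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sigs: list[SignatureSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            genes = frozenset(g for g in fields[2:] if g)
            sigs.append(SignatureSet(fields[0], genes, fields[1]))
    return sigs


def write_gmt(signatures: Iterable[SignatureSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in signatures:
            fh.write("\t".join([s.name, s.source or "na", *sorted(s.genes)]) + "\n")


def signature_enrichment(
    targets: set[str],
    universe: set[str],
    signatures: Sequence[SignatureSet],
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of *targets* in each signature.

    Signatures are intersected with the universe before testing; the
    expected overlap is |targets| * |sig ∩ universe| / |universe|.
    Signatures disjoint from the universe are skipped with a warning.
    q-values are filled in across the tested signatures.
    """
    if not targets <= universe:
        raise ValueError("targets must be a subset of the universe")
    n = len(universe)
    results: list[EnrichmentResult] = []
    for sig in signatures:
        sig_in = sig.genes & universe
        if not sig_in:
            logger.warning("signature %s disjoint from universe; skipped", sig.name)
            continue
        shared = len(targets & sig_in)
        p = overlap_enrichment(n, len(targets), len(sig_in), shared)
        expected = len(targets) * len(sig_in) / n
        results.append(EnrichmentResult(sig.name, shared, len(sig_in), expected, p))
    qs = qvalues([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = q
    return results


def qvalues(
    pvals: Sequence[float],
    pi0: float | None = None,
    lam: float = 0.5,
) -> list[float]:
    """Storey q-values with a fixed-lambda pi0 estimate.

    pi0 (the estimated null proportion) defaults to
    min(1, mean(p > lam) / (1 - lam)); forcing ``pi0=1`` reproduces
    Benjamini-Hochberg adjusted p-values.  q-values are monotone
    non-decreasing along sorted p.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    m = p.size
    if pi0 is None:
        pi0 = min(1.0, float((p > lam).mean()) / (1.0 - lam)) if m > 0 else 1.0
        if pi0 <= 0:
            pi0 = 1.0 / m  # all p small: keep a positive floor
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out.tolist()


def export_enrichment_network(
    results: Sequence[EnrichmentResult],
    signatures: Sequence[SignatureSet],
    universe: set[str],
    fdr: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables of significantly enriched signatures.

    Nodes are signatures with q < fdr, weighted by signature size.
    Edges connect signature pairs weighted by -log10 of their pairwise
    overlap hypergeometric p within the universe; pairs with p = 1
    (weight 0) are dropped.
    """
    sig_by_name = {s.name: s for s in signatures}
    significant = [r for r in results if r.q < fdr]
    nodes = pd.DataFrame(
        [
            {
                "signature": r.signature,
                "size": r.signature_size,
                "overlap": r.overlap,
                "p": r.p,
                "q": r.q,
            }
            for r in significant
        ],
        columns=["signature", "size", "overlap", "p", "q"],
    )
    edges_rows = []
    n = len(universe)
    for i, ra in enumerate(significant):
        ga = sig_by_name[ra.signature].genes & universe
        for rb in significant[i + 1 :]:
            gb = sig_by_name[rb.signature].genes & universe
            shared = len(ga & gb)
            p = overlap_enrichment(n, len(ga), len(gb), shared)
            weight = -np.log10(max(p, 1e-300))
            if weight <= 0:
                continue
            edges_rows.append(
                {
                    "signature_a": ra.signature,
                    "signature_b": rb.signature,
                    "shared": shared,
                    "p": p,
                    "weight": weight,
                }
            )
    edges = pd.DataFrame(
        edges_rows, columns=["signature_a", "signature_b", "shared", "p", "weight"]
    )
    return nodes, edges
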