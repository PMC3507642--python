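"""Synthetic dose-response ChIP experiments with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* a spectrum of binding affinities (log-normal across sites);
* near-nested dose-dependent occupancy — each condition has an affinity
  threshold, weaker sites drop out first, and a small per-site noise
  probability can violate the threshold rule;
* Poisson tag counts per bin with enrichment proportional to affinity at
  occupied sites;
* swapped-channel-style negative peaks whose scores sit strictly below
  any real site, so confidence cutoffs can be calibrated from them;
* conserved elements centred on occupied summits;
* site sequences carrying a palindromic 15-bp element (sharper at
  high-affinity sites) plus a partner element at a preferred
  middle-to-middle spacing;
* expression responses coupled to binding loss in both the activation
  (expression falls when binding is lost) and repression (expression
  rises) directions.

All randomness flows from a single root seed through named substreams,
so emitting one condition never perturbs another.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .conservation import ConservedElement, write_conserved_bed
from .enrichment import SignatureSet, qvalues, write_gmt
from .intervals import CistromeSet, GeneModel, GenomicInterval, Peak, write_peaks
from .motifs import PWM, write_fasta, write_meme_pwm
from .signal import TagTrack, write_bedgraph
from .integration import DETable

__all__ = [
    "DoseCondition",
    "SyntheticConfig",
    "TruthSet",
    "SimulatedCondition",
    "default_are_pwm",
    "default_partner_pwm",
    "generate_truth",
    "synthetic_genome",
    "emit_condition",
    "emit_expression",
    "write_experiment",
]

REFERENCE_LABEL = "R1881+"
MINIMAL_LABEL = "R1881-"


@dataclass(frozen=True)
class DoseCondition:
    """One experimental condition: a label and the affinity quantile
    below which sites are unoccupied (0 = everything bound)."""

    label: str
    quantile: float


# The default dose series mirrors a two-arm agonist design plus an
# antagonist titration: agonist-present (maximal binding), three
# antagonist doses of increasing stringency, and agonist-absent
# (minimal binding, ~13.5% of sites retained).
DEFAULT_DOSES: tuple[DoseCondition, ...] = (
    DoseCondition(REFERENCE_LABEL, 0.0),
    DoseCondition("antagonist_0.1uM", 0.30),
    DoseCondition("antagonist_1uM", 0.60),
    DoseCondition("antagonist_10uM", 0.85),
    DoseCondition(MINIMAL_LABEL, 0.865),
)


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 2_000_000
    n_sites: int = 2000
    # log-normal affinity law: exp(N(mu, sigma))
    affinity_mu: float = 0.3
    affinity_sigma: float = 0.6
    doses: tuple[DoseCondition, ...] = DEFAULT_DOSES
    occupancy_noise: float = 0.02
    # tag-density model
    bin_size: int = 32
    background_rate: float = 0.5  # Poisson lambda per bin outside sites
    enrichment_gain: float = 8.0  # extra lambda per affinity unit at occupied sites
    # peak emission
    site_width: int = 600
    score_base: float = 500.0  # weakest real site's score
    score_scale: float = 550.0  # score span per affinity unit above the minimum
    score_noise_sd: float = 15.0
    fe_base: float = 20.0
    fe_scale: float = 25.0
    n_negative_peaks: int = 300
    # expression coupling
    n_genes: int = 3000
    frac_linked: float = 0.4  # fraction of genes linked 1:1 to a site
    activation_fraction: float = 0.6
    de_fc_mu: float = float(np.log(2.5))  # log-scale location of true |FC|
    de_fc_sigma: float = 0.3
    null_fc_sigma: float = 0.1
    # conservation planting
    conserved_width: int = 300
    conserved_score: float = 0.8
    # sequence / motif planting
    seq_flank: int = 100  # bound sequence = summit +/- flank
    partner_spacing: int = 15  # middle-to-middle bp between the two elements

    def __post_init__(self) -> None:
        if self.n_sites <= 0 or self.n_genes <= 0 or self.n_chroms <= 0:
            raise ValueError("counts must be > 0")
        if not 0 <= self.occupancy_noise < 0.5:
            raise ValueError("occupancy_noise must lie in [0, 0.5)")
        if self.doses[0].quantile != 0.0:
            raise ValueError("first dose condition must be the maximal (quantile 0)")


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named substream: stable across runs and across added conditions."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


def default_are_pwm() -> PWM:
    """A perfectly palindromic 15-bp response-element matrix
    (AGAACAnnnTGTTCT-style inverted repeat with a 3-bp spacer)."""
    consensus = "AGAACANNNTGTTCT"
    probs = np.full((4, 15), 0.05)
    for j, base in enumerate(consensus):
        if base == "N":
            probs[:, j] = 0.25
        else:
            probs["ACGT".index(base), j] = 0.85
    return PWM(probs, pseudocount=0.0, name="ARE_palindrome")


def default_partner_pwm() -> PWM:
    """A forkhead-like partner element (TGTTTAC consensus, 7 bp)."""
    consensus = "TGTTTAC"
    probs = np.full((4, 7), 1.0 / 30)
    for j, base in enumerate(consensus):
        probs["ACGT".index(base), j] = 0.9
    return PWM(probs, pseudocount=0.0, name="FKHD_partner")


@dataclass
class TruthSet:
    """Ground truth of one synthetic experiment."""

    config: SyntheticConfig
    chroms: list[str]
    site_chrom: np.ndarray  # chromosome index per site
    site_summit: np.ndarray
    affinity: np.ndarray
    thresholds: dict[str, float]
    occupancy: dict[str, np.ndarray]  # label -> bool per site
    score: np.ndarray
    fold_enrichment: np.ndarray
    partner_side: np.ndarray  # +1 / -1: side of the partner element
    linked_gene: np.ndarray  # gene index per site, -1 if unlinked
    gene_names: list[str]
    gene_chrom: np.ndarray
    gene_tss: np.ndarray
    gene_strand: np.ndarray  # '+'/'-'
    gene_mode: np.ndarray  # 'activation' / 'repression' / ''
    gene_site: np.ndarray  # site index per gene, -1 if unlinked

    _genome: dict[str, str] | None = field(default=None, repr=False)

    # -- derived truth -----------------------------------------------------

    def site_ids(self) -> list[str]:
        return [f"site{i:05d}" for i in range(len(self.affinity))]

    def lost_sites(self, label: str) -> np.ndarray:
        """Sites occupied in the maximal condition but not under *label*."""
        return self.occupancy[REFERENCE_LABEL] & ~self.occupancy[label]

    def planted_impact(self, label: str) -> float:
        """% of differentially occupied sites (maximal vs minimal) lost
        under *label*, per the truth occupancy."""
        differential = self.occupancy[REFERENCE_LABEL] & ~self.occupancy[MINIMAL_LABEL]
        if differential.sum() == 0:
            raise ValueError("no differential sites in truth")
        lost = differential & ~self.occupancy[label]
        return 100.0 * lost.sum() / differential.sum()

    def planted_targets(self, label: str) -> tuple[set[str], set[str]]:
        """(activation, repression) genes whose linked site is lost
        under *label*."""
        lost = self.lost_sites(label)
        activation, repression = set(), set()
        for gi in range(len(self.gene_names)):
            si = self.gene_site[gi]
            if si < 0 or not lost[si]:
                continue
            if self.gene_mode[gi] == "activation":
                activation.add(self.gene_names[gi])
            else:
                repression.add(self.gene_names[gi])
        return activation, repression

    def gene_models(self) -> list[GeneModel]:
        models = []
        for gi, name in enumerate(self.gene_names):
            chrom = self.chroms[self.gene_chrom[gi]]
            tss = int(self.gene_tss[gi])
            strand = str(self.gene_strand[gi])
            if strand == "+":
                exon = GenomicInterval(chrom, tss, tss + 1500)
            else:
                exon = GenomicInterval(chrom, tss - 1499, tss + 1)
            models.append(GeneModel(name, tss, strand, chrom, (exon,)))
        return models

    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.config.chrom_length for c in self.chroms}


def generate_truth(config: SyntheticConfig) -> TruthSet:
    """Draw site affinities, positions, dose occupancy and gene linkage."""
    cfg = config
    quantiles = [d.quantile for d in cfg.doses]
    if any(b < a for a, b in zip(quantiles, quantiles[1:])):
        raise ValueError("dose thresholds must be monotone non-decreasing")

    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    rng_aff = _rng(cfg.seed, "affinity")
    affinity = rng_aff.lognormal(cfg.affinity_mu, cfg.affinity_sigma, cfg.n_sites)

    # deterministic slot placement: sites cannot overlap by construction
    rng_pos = _rng(cfg.seed, "positions")
    margin = 30_000
    per_chrom = int(np.ceil(cfg.n_sites / cfg.n_chroms))
    usable = cfg.chrom_length - 2 * margin
    slot = usable // per_chrom
    if slot < cfg.site_width + 1000:
        raise ValueError("chromosomes too short for the requested site count")
    site_chrom = np.empty(cfg.n_sites, dtype=int)
    site_summit = np.empty(cfg.n_sites, dtype=int)
    jitter_max = min(800, (slot - cfg.site_width) // 2 - 100)
    for i in range(cfg.n_sites):
        ci, si = i % cfg.n_chroms, i // cfg.n_chroms
        centre = margin + si * slot + slot // 2
        site_chrom[i] = ci
        site_summit[i] = centre + int(rng_pos.integers(-jitter_max, jitter_max + 1))

    thresholds: dict[str, float] = {}
    occupancy: dict[str, np.ndarray] = {}
    for dose in cfg.doses:
        thr = -np.inf if dose.quantile == 0 else float(np.quantile(affinity, dose.quantile))
        occ = affinity >= thr
        if cfg.occupancy_noise > 0:
            rng_noise = _rng(cfg.seed, f"occupancy:{dose.label}")
            flips = rng_noise.random(cfg.n_sites) < cfg.occupancy_noise
            occ = occ ^ flips
        thresholds[dose.label] = thr
        occupancy[dose.label] = occ

    rng_score = _rng(cfg.seed, "scores")
    a0 = affinity.min()
    score = cfg.score_base + cfg.score_scale * (affinity - a0)
    if cfg.score_noise_sd > 0:
        score = score + rng_score.normal(0, cfg.score_noise_sd, cfg.n_sites)
    score = np.maximum(score, cfg.score_base)
    fe = np.maximum(
        cfg.fe_base + cfg.fe_scale * (affinity - a0)
        + rng_score.normal(0, 1.0, cfg.n_sites),
        cfg.fe_base,
    )
    partner_side = np.where(_rng(cfg.seed, "partner").random(cfg.n_sites) < 0.5, 1, -1)

    # gene layout and linkage
    rng_gene = _rng(cfg.seed, "genes")
    n_linked = min(cfg.n_sites, int(round(cfg.frac_linked * cfg.n_genes)))
    linked_sites = rng_gene.permutation(cfg.n_sites)[:n_linked]
    gene_names = [f"G{gi:05d}" for gi in range(cfg.n_genes)]
    gene_chrom = np.empty(cfg.n_genes, dtype=int)
    gene_tss = np.empty(cfg.n_genes, dtype=int)
    gene_strand = np.where(rng_gene.random(cfg.n_genes) < 0.5, "+", "-")
    gene_mode = np.full(cfg.n_genes, "", dtype=object)
    gene_site = np.full(cfg.n_genes, -1, dtype=int)
    linked_gene = np.full(cfg.n_sites, -1, dtype=int)
    for gi in range(cfg.n_genes):
        if gi < n_linked:
            si = int(linked_sites[gi])
            gene_site[gi] = si
            linked_gene[si] = gi
            gene_chrom[gi] = site_chrom[si]
            offset = int(rng_gene.integers(2_000, 20_001))
            sign = 1 if rng_gene.random() < 0.5 else -1
            tss = int(site_summit[si]) + sign * offset
            gene_tss[gi] = int(np.clip(tss, 2000, cfg.chrom_length - 2000))
            gene_mode[gi] = (
                "activation" if rng_gene.random() < cfg.activation_fraction else "repression"
            )
        else:
            gene_chrom[gi] = int(rng_gene.integers(cfg.n_chroms))
            gene_tss[gi] = int(rng_gene.integers(2000, cfg.chrom_length - 2000))
    return TruthSet(
        config=cfg,
        chroms=chroms,
        site_chrom=site_chrom,
        site_summit=site_summit,
        affinity=affinity,
        thresholds=thresholds,
        occupancy=occupancy,
        score=score,
        fold_enrichment=fe,
        partner_side=partner_side,
        linked_gene=linked_gene,
        gene_names=gene_names,
        gene_chrom=gene_chrom,
        gene_tss=gene_tss,
        gene_strand=gene_strand,
        gene_mode=gene_mode,
        gene_site=gene_site,
    )


def _sample_motif(rng: np.random.Generator, pwm: PWM, sharpness: float) -> str:
    """Sample a motif instance; columns are sharpened as p^(1+sharpness)
    so high-affinity sites carry crisper matches."""
    out = []
    for col in pwm.probs.T:
        p = col ** (1.0 + sharpness)
        p = p / p.sum()
        out.append("ACGT"[rng.choice(4, p=p)])
    return "".join(out)


def synthetic_genome(truth: TruthSet) -> dict[str, str]:
    """Random genome with the palindromic element implanted at every
    site summit and the partner element at the configured spacing.
    Cached on the truth set (deterministic given the seed)."""
    if truth._genome is not None:
        return truth._genome
    cfg = truth.config
    rng = _rng(cfg.seed, "genome")
    are = default_are_pwm()
    partner = default_partner_pwm()
    base_lookup = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome: dict[str, list[str] | str] = {}
    raw: dict[str, np.ndarray] = {}
    for chrom in truth.chroms:
        raw[chrom] = base_lookup[rng.integers(0, 4, cfg.chrom_length, dtype=np.uint8)].copy()
    rng_motif = _rng(cfg.seed, "motif_instances")
    for i in range(len(truth.affinity)):
        chrom = truth.chroms[truth.site_chrom[i]]
        summit = int(truth.site_summit[i])
        arr = raw[chrom]
        are_inst = _sample_motif(rng_motif, are, float(truth.affinity[i]))
        a_start = summit - are.width // 2
        arr[a_start : a_start + are.width] = np.frombuffer(are_inst.encode(), dtype=np.uint8)
        partner_inst = _sample_motif(rng_motif, partner, 1.0)
        # middle-to-middle spacing; ARE middle sits at the summit
        p_mid = summit + int(truth.partner_side[i]) * cfg.partner_spacing
        p_start = p_mid - (partner.width - 1) // 2
        arr[p_start : p_start + partner.width] = np.frombuffer(
            partner_inst.encode(), dtype=np.uint8
        )
    truth._genome = {c: a.tobytes().decode("ascii") for c, a in raw.items()}
    return truth._genome


@dataclass
class SimulatedCondition:
    label: str
    track: TagTrack
    positive: CistromeSet
    negative: CistromeSet
    sequences: dict[str, tuple[str, str]]  # site id -> (chrom, sequence)
    conserved: list[ConservedElement]


def emit_condition(truth: TruthSet, label: str, config: SyntheticConfig | None = None) -> SimulatedCondition:
    """Emit the observable data of one condition: tag track, positive
    and negative peak sets, bound-site sequences and conserved elements."""
    cfg = config or truth.config
    if label not in truth.occupancy:
        raise KeyError(f"unknown condition {label!r}")
    occ = truth.occupancy[label]
    half = cfg.site_width // 2
    bs = cfg.bin_size
    n_bins = int(np.ceil(cfg.chrom_length / bs))

    rng_track = _rng(cfg.seed, f"track:{label}")
    counts = {
        c: rng_track.poisson(cfg.background_rate, n_bins).astype(np.int64)
        for c in truth.chroms
    }
    for i in np.flatnonzero(occ):
        chrom = truth.chroms[truth.site_chrom[i]]
        start = int(truth.site_summit[i]) - half
        end = start + cfg.site_width
        b0, b1 = start // bs, (end - 1) // bs
        lam = cfg.enrichment_gain * float(truth.affinity[i])
        counts[chrom][b0 : b1 + 1] += rng_track.poisson(lam, b1 - b0 + 1)
    track = TagTrack(bin_size=bs, extension=cfg.site_width // 3, counts=counts,
                     total_tags=int(sum(v.sum() for v in counts.values())))

    ids = truth.site_ids()
    peaks = []
    for i in np.flatnonzero(occ):
        chrom = truth.chroms[truth.site_chrom[i]]
        summit = int(truth.site_summit[i])
        peaks.append(
            Peak(
                GenomicInterval(chrom, summit - half, summit + half),
                summit,
                float(truth.score[i]),
                float(truth.fold_enrichment[i]),
                ids[i],
            )
        )
    positive = CistromeSet(label, peaks)

    rng_neg = _rng(cfg.seed, f"negatives:{label}")
    neg_peaks = []
    for j in range(cfg.n_negative_peaks):
        chrom = truth.chroms[int(rng_neg.integers(cfg.n_chroms))]
        start = int(rng_neg.integers(1000, cfg.chrom_length - 1400))
        neg_peaks.append(
            Peak(
                GenomicInterval(chrom, start, start + 400),
                start + 200,
                float(rng_neg.uniform(100, cfg.score_base * 0.9)),
                float(rng_neg.uniform(2, cfg.fe_base * 0.9)),
                f"neg{j:04d}",
            )
        )
    negative = CistromeSet(f"{label}|swapped", neg_peaks)

    genome = synthetic_genome(truth)
    sequences = {}
    for i in np.flatnonzero(occ):
        chrom = truth.chroms[truth.site_chrom[i]]
        summit = int(truth.site_summit[i])
        seq = genome[chrom][summit - cfg.seq_flank : summit + cfg.seq_flank]
        sequences[ids[i]] = (chrom, seq)

    cons_half = cfg.conserved_width // 2
    conserved = [
        ConservedElement(
            GenomicInterval(
                truth.chroms[truth.site_chrom[i]],
                int(truth.site_summit[i]) - cons_half,
                int(truth.site_summit[i]) + cons_half,
            ),
            cfg.conserved_score,
        )
        for i in np.flatnonzero(occ)
    ]
    return SimulatedCondition(label, track, positive, negative, sequences, conserved)


def emit_expression(truth: TruthSet, label: str, config: SyntheticConfig | None = None) -> DETable:
    """Differential-expression table (treated condition vs maximal
    binding reference) coupled to binding loss.

    Genes whose linked site is lost under *label* respond with |FC|
    above the significance cut in expectation — down for activation
    targets, up for repression targets — and small p-values; all other
    genes are null (uniform p, |FC| near 1).  q-values are
    Benjamini-Hochberg over the emitted p-values.
    """
    cfg = config or truth.config
    rng = _rng(cfg.seed, f"expression:{label}")
    lost = truth.lost_sites(label)
    n = len(truth.gene_names)
    fc = np.empty(n)
    d = np.empty(n)
    p = np.empty(n)
    for gi in range(n):
        si = truth.gene_site[gi]
        if si >= 0 and lost[si]:
            mag = float(np.exp(rng.normal(cfg.de_fc_mu, cfg.de_fc_sigma)))
            sign = -1.0 if truth.gene_mode[gi] == "activation" else 1.0
            fc[gi] = sign * max(mag, 1.0 + 1e-9)
            d[gi] = sign * rng.normal(5.0, 1.0)
            p[gi] = 10.0 ** (-rng.uniform(3.0, 8.0))
        else:
            r = float(np.exp(rng.normal(0.0, cfg.null_fc_sigma)))
            fc[gi] = r if r >= 1 else -1.0 / r
            d[gi] = rng.normal(0.0, 1.0)
            p[gi] = rng.uniform()
    q = qvalues(p, pi0=1.0)
    df = pd.DataFrame(
        {
            "probe_id": [f"P{gi:05d}_at" for gi in range(n)],
            "gene": truth.gene_names,
            "fold_change": fc,
            "d_score": d,
            "q_value": q,
            "p_value": p,  # raw p, kept for diagnostics of the generator
        }
    )
    return DETable(df)


# ---------------------------------------------------------------------------
# On-disk experiment


def _write_refflat(models: Sequence[GeneModel], path: Path) -> None:
    with open(path, "w") as fh:
        for g in models:
            starts = ",".join(str(e.start) for e in g.exons) + ","
            ends = ",".join(str(e.end) for e in g.exons) + ","
            fh.write(
                f"{g.gene}\t{g.gene}_tx\t{g.chrom}\t{g.strand}\t{g.tx_start}\t"
                f"{g.tx_end}\t{g.tx_start}\t{g.tx_end}\t{len(g.exons)}\t{starts}\t{ends}\n"
            )


def write_experiment(config: SyntheticConfig, outdir: str | Path,
                     target_dose: str | None = None) -> TruthSet:
    """Generate a full synthetic experiment on disk.

    Writes, per condition: peaks, swapped-channel negatives, tag track,
    bound-sequence FASTA and conserved-element BED; plus the genome
    FASTA, gene models, DE tables for the antagonist conditions, the
    planted motif matrices, gene signatures and a truth JSON.
    Returns the in-memory truth set.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = generate_truth(config)
    genome = synthetic_genome(truth)

    with open(outdir / "chrom_sizes.tsv", "w") as fh:
        for c, size in truth.chrom_sizes().items():
            fh.write(f"{c}\t{size}\n")
    write_fasta(genome, outdir / "genome.fasta")
    _write_refflat(truth.gene_models(), outdir / "genes.refflat")
    write_meme_pwm(default_are_pwm(), outdir / "are_pwm.meme")
    write_meme_pwm(default_partner_pwm(), outdir / "partner_pwm.meme")

    target_dose = target_dose or config.doses[-2].label  # highest antagonist dose
    for dose in config.doses:
        cond = emit_condition(truth, dose.label, config)
        tag = dose.label.replace("+", "plus").replace("-", "minus")
        write_peaks(cond.positive, outdir / f"peaks_{tag}.bed")
        write_peaks(cond.negative, outdir / f"negatives_{tag}.bed")
        write_bedgraph(cond.track, outdir / f"track_{tag}.bedgraph")
        write_fasta(
            {f"{sid}|{chrom}": seq for sid, (chrom, seq) in cond.sequences.items()},
            outdir / f"bound_{tag}.fasta",
        )
        write_conserved_bed(cond.conserved, outdir / f"conserved_{tag}.bed")
        if dose.label not in (REFERENCE_LABEL,):
            emit_expression(truth, dose.label, config).to_tsv(outdir / f"de_{tag}.tsv")

    # gene signatures: cores of the planted targets plus random controls
    act, rep = truth.planted_targets(target_dose)
    rng = _rng(config.seed, "signatures")
    all_genes = list(truth.gene_names)
    sigs = []
    if act:
        core = sorted(act)[: min(80, len(act))]
        sigs.append(SignatureSet("planted_activation_core", frozenset(core), "synthetic"))
    if rep:
        core = sorted(rep)[: min(80, len(rep))]
        sigs.append(SignatureSet("planted_repression_core", frozenset(core), "synthetic"))
    for k in range(2):
        pick = rng.choice(len(all_genes), size=100, replace=False)
        sigs.append(
            SignatureSet(f"random_set_{k + 1}", frozenset(all_genes[i] for i in pick), "synthetic")
        )
    write_gmt(sigs, outdir / "signatures.gmt")

    truth_json = {
        "seed": config.seed,
        "doses": [d.label for d in config.doses],
        "thresholds": {k: (None if np.isinf(v) else v) for k, v in truth.thresholds.items()},
        "n_sites": int(config.n_sites),
        "occupied_counts": {k: int(v.sum()) for k, v in truth.occupancy.items()},
        "planted_impact": {
            d.label: truth.planted_impact(d.label)
            for d in config.doses
            if d.label != REFERENCE_LABEL
        },
        "planted_targets": {
            "dose": target_dose,
            "activation": sorted(act),
            "repression": sorted(rep),
        },
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=1)
    return truth
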