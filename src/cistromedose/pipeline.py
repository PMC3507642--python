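"""End-to-end orchestration: filter -> quantify -> compare -> conserve
-> motif -> integrate -> enrich, from a single config, with a
reproducibility report.

The pipeline consumes the on-disk artifact layout the synthetic
generator writes (and which real data can be converted into): per
condition a peak BED, a swapped-channel negative BED and a bedGraph tag
track, plus gene models, conserved elements, bound-sequence FASTA, a
genome FASTA, motif matrices, a differential-expression TSV and a GMT
signature collection.  All stage outputs are aggregated into a JSON
report; deterministic stages are byte-reproducible for a fixed config
and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import stats as _stats

from . import cistrome as cz
from . import conservation as cv
from . import integration as ig
from . import motifs as mt
from . import signal as sg
from .enrichment import read_gmt, signature_enrichment
from .intervals import CistromeSet, map_to_tss, overlap_sets, read_peaks, read_refflat

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "validate_config", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run.

    ``conditions`` maps condition label to a dict with keys ``peaks``,
    ``negatives`` and ``track``; ``max_condition``/``min_condition``
    name the maximal and minimal cistromes and ``treated_conditions``
    the antagonist doses in increasing order.
    """

    data_dir: str = "."
    conditions: dict[str, dict[str, str]] = field(default_factory=dict)
    max_condition: str = "R1881+"
    min_condition: str = "R1881-"
    treated_conditions: list[str] = field(default_factory=list)
    target_dose: str = ""  # dose used for target classification; default: last treated
    chrom_sizes: str = "chrom_sizes.tsv"
    refflat: str = "genes.refflat"
    conserved_elements: str = ""  # BED5 for the maximal condition
    bound_fasta: str = ""  # bound sequences of the maximal condition
    genome_fasta: str = ""
    are_pwm: str = ""
    partner_pwm: str = ""
    de_table: str = ""  # DE of the target dose vs reference
    signatures: str = ""
    # thresholds
    auto_thresholds: bool = True
    score_cut: float = 500.0
    fe_cut: float = 20.0
    fdr: float = 0.05
    fc_cut: float = 1.5
    tss_max_dist: int = 25_000
    bin_size: int = 32
    trend_window: int = 100
    zscore_groups: int = 100
    zscore_max_seqs: int = 500
    seed: int = 0
    # stage toggles
    stages: list[str] = field(
        default_factory=lambda: [
            "filter", "impact", "signal", "conservation", "motif",
            "integration", "enrichment",
        ]
    )

    def path(self, rel: str) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else Path(self.data_dir) / rel

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of problems; empty iff the config is runnable."""
    problems: list[str] = []
    for label in [config.max_condition, config.min_condition, *config.treated_conditions]:
        entry = config.conditions.get(label)
        if entry is None:
            problems.append(f"conditions: missing entry for {label!r}")
            continue
        for key in ("peaks", "negatives", "track"):
            rel = entry.get(key)
            if not rel:
                problems.append(f"conditions[{label!r}]: missing {key} path")
            elif not config.path(rel).exists():
                problems.append(f"conditions[{label!r}].{key}: file not found: {rel}")
    for name in ("chrom_sizes", "refflat"):
        rel = getattr(config, name)
        if not rel or not config.path(rel).exists():
            problems.append(f"{name}: file not found: {rel}")
    for name in ("conserved_elements", "bound_fasta", "genome_fasta",
                 "are_pwm", "partner_pwm", "de_table", "signatures"):
        rel = getattr(config, name)
        if rel and not config.path(rel).exists():
            problems.append(f"{name}: file not found: {rel}")
    for name in ("fdr", "fc_cut", "score_cut", "fe_cut"):
        if getattr(config, name) < 0:
            problems.append(f"{name}: must be >= 0")
    if not 0 < config.fdr <= 1:
        problems.append("fdr: must lie in (0, 1]")
    if config.tss_max_dist <= 0:
        problems.append("tss_max_dist: must be > 0")
    if config.target_dose and config.target_dose not in config.treated_conditions:
        problems.append("target_dose: not among treated_conditions")
    return problems


@dataclass
class RunReport:
    config: dict
    site_counts: dict[str, int] = field(default_factory=dict)
    raw_site_counts: dict[str, int] = field(default_factory=dict)
    thresholds: dict[str, dict[str, float]] = field(default_factory=dict)
    impact: dict[str, dict] = field(default_factory=dict)
    min_subset_fraction: float = float("nan")
    strength_bias_p: float = float("nan")
    trend: dict[str, dict] = field(default_factory=dict)
    conservation: dict = field(default_factory=dict)
    motif: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)
    targets: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)
    input_checksums: dict[str, str] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    failed_stages: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _read_chrom_sizes(path: Path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                c, s = line.split("\t")
                sizes[c] = int(s)
    return sizes


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> RunReport:
    """Execute the configured stages in dependency order.

    Raises on a broken config; a failure inside an optional downstream
    stage is recorded in ``failed_stages`` and the remaining stages
    still run.  Returns the aggregated report (also written to
    ``outdir/report.json`` when *outdir* is given).
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config:\n" + "\n".join(problems))
    report = RunReport(config=dataclasses.asdict(config))
    t_all = time.time()

    for label, entry in config.conditions.items():
        for key in ("peaks", "negatives", "track"):
            p = config.path(entry[key])
            report.input_checksums[f"{label}:{key}"] = _checksum(p)

    # ---- filter ----------------------------------------------------------
    t0 = time.time()
    hc: dict[str, CistromeSet] = {}
    labels = [config.max_condition, config.min_condition, *config.treated_conditions]
    for label in labels:
        entry = config.conditions[label]
        pos = read_peaks(config.path(entry["peaks"]), label=label)
        neg = read_peaks(config.path(entry["negatives"]), label=f"{label}|neg")
        report.raw_site_counts[label] = len(pos)
        if config.auto_thresholds:
            thr = cz.auto_thresholds(neg)
        else:
            thr = cz.FilterThresholds(config.score_cut, config.fe_cut)
        hc[label] = cz.filter_high_confidence(pos, neg, thr)
        report.site_counts[label] = len(hc[label])
        report.thresholds[label] = {"score_cut": thr.score_cut, "fe_cut": thr.fe_cut}
    report.stage_seconds["filter"] = time.time() - t0

    max_hc, min_hc = hc[config.max_condition], hc[config.min_condition]

    # ---- impact ----------------------------------------------------------
    if "impact" in config.stages:
        t0 = time.time()
        ov = overlap_sets(max_hc, min_hc)
        report.min_subset_fraction = (
            ov.shared_b / len(min_hc) if len(min_hc) else float("nan")
        )
        bound = [p.score for p in max_hc if p.id in ov.mapping]
        unbound = [p.score for p in max_hc if p.id not in ov.mapping]
        if bound and unbound:
            report.strength_bias_p = cz.compare_strength_groups(bound, unbound).p_value
        for label in config.treated_conditions:
            res = cz.percent_impact(max_hc, min_hc, hc[label])
            report.impact[label] = {
                "differential_sites": res.differential_sites,
                "lost_in_treated": res.lost_in_treated,
                "percent_impact": res.percent_impact,
            }
        report.stage_seconds["impact"] = time.time() - t0

    # ---- signal / dose trends -------------------------------------------
    if "signal" in config.stages:
        t0 = time.time()
        sizes = _read_chrom_sizes(config.path(config.chrom_sizes))
        ref_track = sg.read_bedgraph(
            config.path(config.conditions[config.max_condition]["track"]),
            sizes, config.bin_size,
        )
        ordered = cz.sort_by_strength(max_hc)
        ref_signal = {p.id: sg.site_signal(ref_track, p).signal for p in ordered}
        for label in config.treated_conditions:
            track = sg.read_bedgraph(
                config.path(config.conditions[label]["track"]), sizes, config.bin_size
            )
            fcs = [
                sg.signed_fold_change(
                    sg.site_signal(track, p).signal, ref_signal[p.id], p.id
                )
                for p in ordered
            ]
            trend = sg.dose_trend(fcs, window=min(config.trend_window, len(fcs)))
            ranks = np.arange(trend.moving_average.size)
            rho, rho_p = _stats.spearmanr(ranks, np.abs(trend.moving_average))
            report.trend[label] = {
                "n_sites": len(fcs),
                "slope": trend.slope,
                "spearman_rank_vs_abs_fc": float(rho),
                "spearman_p": float(rho_p),
            }
        report.stage_seconds["signal"] = time.time() - t0

    # ---- conservation ----------------------------------------------------
    if "conservation" in config.stages and config.conserved_elements:
        t0 = time.time()
        try:
            track = cv.read_conserved_bed(config.path(config.conserved_elements))
            profile = cv.mean_profile(max_hc, track)
            centre = int(np.flatnonzero(profile.offsets == 0)[0])
            report.conservation = {
                "value_at_summit": float(profile.values[centre]),
                "value_at_500bp": float(
                    profile.values[centre + 5] + profile.values[centre - 5]
                ) / 2.0,
                "value_at_5kb": float(
                    profile.values[centre + 50] + profile.values[centre - 50]
                ) / 2.0,
                "profile_offsets": profile.offsets.tolist(),
                "profile_values": profile.values.tolist(),
            }
        except Exception as exc:  # pragma: no cover - defensive
            report.failed_stages["conservation"] = str(exc)
        report.stage_seconds["conservation"] = time.time() - t0

    # ---- motif -----------------------------------------------------------
    if "motif" in config.stages and config.bound_fasta and config.are_pwm:
        t0 = time.time()
        try:
            raw_seqs = mt.read_fasta(config.path(config.bound_fasta))
            bound: dict[str, tuple[str, str]] = {}
            for sid, seq in raw_seqs.items():
                name, _, chrom = sid.partition("|")
                bound[name] = (chrom or name, seq)
            are = mt.read_meme_pwm(config.path(config.are_pwm))
            genome = (
                mt.read_fasta(config.path(config.genome_fasta))
                if config.genome_fasta
                else {}
            )
            sub = dict(list(bound.items())[: config.zscore_max_seqs])
            z = mt.motif_zscore(
                sub, are, genome,
                background_groups=config.zscore_groups, seed=config.seed,
            )
            report.motif = {
                "are_zscore": z.z,
                "bound_with_motif": z.bound_count,
                "n_scanned": len(sub),
                "random_mean": z.random_mean,
                "random_sd": z.random_sd,
            }
            if config.partner_pwm:
                partner = mt.read_meme_pwm(config.path(config.partner_pwm))
                plain = {sid: seq for sid, (_, seq) in bound.items()}
                hits_a = [h for hl in mt.scan_sequences(plain, are).values() for h in hl]
                hits_b = [h for hl in mt.scan_sequences(plain, partner).values() for h in hl]
                hist = mt.pair_spacing(hits_a, hits_b)
                report.motif["pair_spacing_mode"] = hist.mode
                report.motif["pair_spacing_counts"] = hist.counts.tolist()
        except Exception as exc:  # pragma: no cover - defensive
            report.failed_stages["motif"] = str(exc)
        report.stage_seconds["motif"] = time.time() - t0

    # ---- integration -----------------------------------------------------
    targets = []
    de = None
    if "integration" in config.stages and config.de_table:
        t0 = time.time()
        de = ig.DETable.from_tsv(config.path(config.de_table))
        up, down = ig.de_significant(de, config.fdr, config.fc_cut)
        report.expression = {"n_up": len(up), "n_down": len(down)}
        dose = config.target_dose or (
            config.treated_conditions[-1] if config.treated_conditions else ""
        )
        if dose:
            ov_t = overlap_sets(max_hc, hc[dose])
            impacted = [p for p in max_hc if p.id not in ov_t.mapping]
            genes = read_refflat(config.path(config.refflat))
            impacted_map = map_to_tss(
                CistromeSet("impacted", impacted), genes, config.tss_max_dist
            )
            targets = ig.classify_direct_targets(impacted_map, up, down)
            report.targets = {
                "dose": dose,
                "n_impacted_sites": len(impacted),
                "n_activation": sum(t.mode == "activation" for t in targets),
                "n_repression": sum(t.mode == "repression" for t in targets),
                "activation_genes": sorted(
                    t.gene for t in targets if t.mode == "activation"
                ),
                "repression_genes": sorted(
                    t.gene for t in targets if t.mode == "repression"
                ),
            }
        report.stage_seconds["integration"] = time.time() - t0

    # ---- enrichment ------------------------------------------------------
    if "enrichment" in config.stages and config.signatures and de is not None:
        t0 = time.time()
        sigs = read_gmt(config.path(config.signatures))
        universe = set(de.df["gene"])
        for mode in ("activation", "repression"):
            tset = {t.gene for t in targets if t.mode == mode} & universe
            if not tset:
                continue
            results = signature_enrichment(tset, universe, sigs)
            report.enrichment[mode] = [
                {
                    "signature": r.signature,
                    "overlap": r.overlap,
                    "expected": r.expected,
                    "p": r.p,
                    "q": r.q,
                }
                for r in sorted(results, key=lambda r: r.p)
            ]
        report.stage_seconds["enrichment"] = time.time() - t0

    report.stage_seconds["total"] = time.time() - t_all
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_json(outdir / "report.json")
    return report
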