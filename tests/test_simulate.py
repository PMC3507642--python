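"""Ground-truth generation and condition emission."""

import numpy as np
import pytest
from scipy import stats

from cistromedose.cistrome import auto_thresholds, filter_high_confidence
from cistromedose.integration import de_significant
from cistromedose.simulate import (
    DoseCondition,
    SyntheticConfig,
    emit_condition,
    emit_expression,
    generate_truth,
    synthetic_genome,
)

ORDER = ["R1881+", "antagonist_0.1uM", "antagonist_1uM", "antagonist_10uM", "R1881-"]


class TestGenerateTruth:
    def test_noise_free_occupancy_is_strictly_nested(self):
        truth = generate_truth(SyntheticConfig(seed=2, n_sites=500, n_chroms=2,
                                               chrom_length=1_200_000, n_genes=600,
                                               occupancy_noise=0.0))
        for lo, hi in zip(ORDER, ORDER[1:]):
            assert np.all(~truth.occupancy[hi] | truth.occupancy[lo])
            assert truth.occupancy[hi].sum() < truth.occupancy[lo].sum()

    def test_deterministic_given_seed(self, small_config, small_truth):
        again = generate_truth(small_config)
        assert np.array_equal(again.affinity, small_truth.affinity)
        assert np.array_equal(again.site_summit, small_truth.site_summit)
        for k, v in small_truth.occupancy.items():
            assert np.array_equal(again.occupancy[k], v)
        assert np.array_equal(again.gene_site, small_truth.gene_site)

    def test_median_threshold_plants_half_impact(self):
        cfg = SyntheticConfig(
            seed=4, n_sites=1000, n_chroms=2, chrom_length=2_400_000,
            n_genes=1000, occupancy_noise=0.0,
            doses=(
                DoseCondition("R1881+", 0.0),
                DoseCondition("half", 0.5),
                DoseCondition("R1881-", 0.9),
            ),
        )
        truth = generate_truth(cfg)
        assert truth.planted_impact("half") == pytest.approx(50 / 0.9, abs=1.5)

    def test_non_monotone_thresholds_rejected(self):
        cfg = SyntheticConfig(
            doses=(DoseCondition("R1881+", 0.0), DoseCondition("a", 0.5),
                   DoseCondition("b", 0.3)),
        )
        with pytest.raises(ValueError):
            generate_truth(cfg)

    def test_affinity_follows_lognormal_law(self, small_truth, small_config):
        logs = np.log(small_truth.affinity)
        assert np.mean(logs) == pytest.approx(small_config.affinity_mu, abs=0.15)
        assert np.std(logs) == pytest.approx(small_config.affinity_sigma, abs=0.15)


class TestEmitCondition:
    def test_background_bins_match_poisson_rate(self, small_truth, small_config):
        cond = emit_condition(small_truth, "R1881-")
        # mask out site neighbourhoods; the rest is pure background
        bs = small_config.bin_size
        mask = {c: np.ones(v.size, dtype=bool) for c, v in cond.track.counts.items()}
        for i in range(len(small_truth.affinity)):
            c = small_truth.chroms[small_truth.site_chrom[i]]
            b = int(small_truth.site_summit[i]) // bs
            mask[c][max(0, b - 30) : b + 30] = False
        vals = np.concatenate([cond.track.counts[c][m] for c, m in mask.items()])
        se = np.sqrt(small_config.background_rate / vals.size)
        assert abs(vals.mean() - small_config.background_rate) < 3 * se

    def test_strongest_site_has_highest_score(self, small_truth):
        cond = emit_condition(small_truth, "R1881+")
        occupied = np.flatnonzero(small_truth.occupancy["R1881+"])
        top_truth = occupied[np.argmax(small_truth.affinity[occupied])]
        best_peak = max(cond.positive, key=lambda p: p.score)
        assert best_peak.id == f"site{top_truth:05d}"

    def test_auto_filter_excludes_all_negatives_keeps_all_positives(self, small_truth):
        for label in ORDER:
            cond = emit_condition(small_truth, label)
            thr = auto_thresholds(cond.negative)
            kept = filter_high_confidence(cond.positive, cond.negative, thr)
            assert len(kept) == len(cond.positive)
            assert len(filter_high_confidence(cond.negative, cond.negative, thr)) == 0

    def test_bound_sequences_carry_planted_element(self, small_truth):
        from cistromedose.motifs import scan_sequences
        from cistromedose.simulate import default_are_pwm

        cond = emit_condition(small_truth, "antagonist_1uM")
        seqs = {sid: seq for sid, (_, seq) in cond.sequences.items()}
        hits = scan_sequences(seqs, default_are_pwm())
        frac = np.mean([len(h) > 0 for h in hits.values()])
        assert frac > 0.95

    def test_conserved_elements_centred_on_occupied_summits(self, small_truth, small_config):
        cond = emit_condition(small_truth, "R1881+")
        occ = np.flatnonzero(small_truth.occupancy["R1881+"])
        assert len(cond.conserved) == occ.size
        el = cond.conserved[0]
        summit = small_truth.site_summit[occ[0]]
        assert el.interval.start == summit - small_config.conserved_width // 2

    def test_unknown_condition_rejected(self, small_truth):
        with pytest.raises(KeyError):
            emit_condition(small_truth, "no_such_dose")


class TestEmitExpression:
    def test_lost_activation_genes_go_down(self, small_truth):
        de = emit_expression(small_truth, "antagonist_10uM")
        lost = small_truth.lost_sites("antagonist_10uM")
        df = de.df.set_index("gene")
        fcs = []
        for gi, name in enumerate(small_truth.gene_names):
            si = small_truth.gene_site[gi]
            if si >= 0 and lost[si] and small_truth.gene_mode[gi] == "activation":
                fcs.append(df.loc[name, "fold_change"])
        assert fcs and np.all(np.array(fcs) < 0)
        assert np.mean(np.abs(fcs)) > 1.5

    def test_null_gene_qvalues_mostly_large(self):
        cfg = SyntheticConfig(seed=5, n_sites=50, n_chroms=2, chrom_length=300_000,
                              n_genes=5000, frac_linked=0.0)
        truth = generate_truth(cfg)
        de = emit_expression(truth, "antagonist_10uM")
        up, down = de_significant(de)
        assert len(up) + len(down) <= 3  # null-only table: essentially nothing passes

    def test_untreated_condition_has_no_planted_signal(self, small_truth):
        de = emit_expression(small_truth, "R1881+")
        up, down = de_significant(de)
        assert len(up) + len(down) <= 2


def test_null_pvalues_uniform_ks():
    """Unlinked genes must carry uniform p-values."""
    cfg = SyntheticConfig(seed=6, n_sites=50, n_chroms=2, chrom_length=300_000,
                          n_genes=5000, frac_linked=0.0)
    truth = generate_truth(cfg)
    de = emit_expression(truth, "antagonist_10uM")
    ks = stats.kstest(de.df["p_value"].to_numpy(), "uniform")
    assert ks.pvalue > 0.01


def test_genome_motifs_at_every_summit(small_truth):
    from cistromedose.motifs import scan_pwm
    from cistromedose.simulate import default_are_pwm

    genome = synthetic_genome(small_truth)
    pwm = default_are_pwm()
    found = 0
    for i in range(30):
        chrom = small_truth.chroms[small_truth.site_chrom[i]]
        s = int(small_truth.site_summit[i])
        window = genome[chrom][s - 20 : s + 20]
        if scan_pwm(window, pwm):
            found += 1
    assert found >= 28
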