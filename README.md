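# cistromedose

Dose-dependent comparative cistrome analysis: quantify how
small-molecule antagonism reshapes a transcription factor's genome-wide
binding landscape, and integrate binding impact with differential
expression to classify direct activation and repression targets.

The package is aimed at regulatory-genomics analysts working with
ChIP-seq of a drug-targeted transcription factor (the motivating case
is a nuclear receptor under antagonist titration) who need to move from
per-condition peak lists to a quantitative dose-response story:

* **High-confidence filtering** against "negative" peaks called with
  ChIP and control channels swapped — joint score/fold-enrichment
  cutoffs, auto-calibrated so every negative peak is excluded.
* **% impact**: with maximal and minimal cistromes M and m, the
  differential sites are D = {s ∈ M : s ∩ m = ∅} (overlap = sharing
  ≥ 1 bp), and for a treated cistrome T,
  `% impact = 100 · |{s ∈ D : s ∩ T = ∅}| / |D|`.
* **Robust per-site signal**: tag density in 32-nt bins combined with
  the one-step Tukey biweight S = Σwᵢxᵢ/Σwᵢ, wᵢ = (1 − uᵢ²)² for
  |uᵢ| < 1, uᵢ = (xᵢ − median)/(5·MAD + ε); signed fold changes
  (−1/ratio convention) and moving-average trends along descending
  binding strength.
* **Conservation profiles** sampled every 100 bp within ±10 kb of peak
  summits from a scored conserved-element track.
* **Motif statistics**: log-odds PWM scanning on both strands,
  palindrome detection, specificity Z-scores against 100 random
  sequence groups matched in number/length/chromosome, and
  middle-to-middle element-pair spacing (10–50 bp).
* **Direct targets**: genes with drug-impacted binding within 25 kb of
  the TSS whose expression is significantly down- (activation targets)
  or up-regulated (repression targets) at FDR < 0.05, |FC| > 1.5;
  hypergeometric signature enrichment with Storey q-values and a
  network export of enriched signatures.
* **A synthetic-data generator** with known ground truth (affinity
  spectrum, nested dose occupancy, Poisson tags, planted palindromic
  motif + partner element, coupled expression) so the entire pipeline
  runs and is validated without any download.

## Worked example

```python
from cistromedose import (
    SyntheticConfig, write_experiment, qpcr_concordance, load_table1,
)
from cistromedose.simulate import generate_truth, emit_condition
from cistromedose.cistrome import filter_high_confidence, percent_impact

truth = generate_truth(SyntheticConfig(seed=1))
conds = {lab: emit_condition(truth, lab)
         for lab in ("R1881+", "R1881-", "antagonist_1uM")}
hc = {lab: filter_high_confidence(c.positive, c.negative, "auto")
      for lab, c in conds.items()}
res = percent_impact(hc["R1881+"], hc["R1881-"], hc["antagonist_1uM"])
print(len(hc["R1881+"]), len(hc["R1881-"]))
print(f"{res.lost_in_treated}/{res.differential_sites} "
      f"= {res.percent_impact:.2f}% impact")

conc = qpcr_concordance(load_table1())
print(f"qPCR concordance r={conc.r:.3f} (n={conc.n})")
```

prints

```
1955 308
1133/1654 = 68.50% impact
qPCR concordance r=0.870 (n=11)
```

i.e. 1955 of 2000 synthetic sites survive high-confidence filtering in
the maximal-binding condition and 308 in the minimal one; at the middle
antagonist dose 68.5% of the differentially occupied sites are lost;
and on the packaged twelve-site qPCR validation table the peak-caller
binding score correlates r = 0.87 with bench enrichment over the eleven
sites carrying both values.

The same flow is available from the shell:

```bash
cistromedose simulate --out exp/ --seed 1
cistromedose impact --max exp/peaks_R1881plus.bed \
    --min exp/peaks_R1881minus.bed --treated exp/peaks_antagonist_1uM.bed
cistromedose run --config run.yaml --out results/
```

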