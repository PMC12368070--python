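# polvel — Pol II elongation-velocity analysis from TT-seq and mNET-seq

`polvel` estimates changes in RNA polymerase II elongation velocity from
paired nascent-transcription assays. It is written for transcription labs
that profile acute perturbations (degron depletions of elongation factors,
drug treatments) with:

* **TT-seq** — a short 4sU pulse labels newly made RNA; coverage of the
  purified, fragmented labeled RNA measures RNA *synthesis*;
* **mNET-seq** — immunoprecipitation of engaged Pol II; the 3′ (last
  incorporated) base of the nascent RNA marks the polymerase active site,
  giving single-nucleotide Pol II *occupancy*;
* **ChIP-seq** — Pol II or chromatin-mark occupancy as an orthogonal
  readout.

## The statistic

At steady state, occupancy and synthesis obey

```
mNET signal  ∝  I / v        (polymerases accumulate where they move slowly)
TT-seq signal ∝ I            (synthesis during a fixed pulse)
```

with I the initiation rate and v the elongation velocity, so the ratio

```
v̂  =  (TT-seq midpoint coverage / sf_TT) / (mNET-seq coverage / sf_mNET)
```

tracks elongation velocity up to a global constant. `polvel` computes v̂
per 50-bp genome bin (heatmaps) and per gene (counts in the gene body
excluding the first kilobase), with per-sample size factors `sf` estimated
by median-of-ratios on labeled spike-ins — the anchor that keeps *global*
velocity shifts visible. Condition contrasts are reported as per-gene
log2(v̂_treated / v̂_control) with a one-sample Wilcoxon test, boxplot
summaries (type-7 hinges, 1.58·IQR/√n notches), bootstrap metagene
profiles (10,000 iterations, percentile 95% bands) and TSS-aligned /
gene-center-aligned change heatmaps.

Because public nascent-seq datasets cannot certify a velocity estimator
(truth is unknown), `polvel` ships a trajectory-level simulator:
polymerases initiate as a Poisson process, move along a piecewise-constant
velocity profile (optionally rescaled at a depletion onset time), and are
read out exactly as the assays would — labeled fragments for TT-seq,
active-site tags for mNET-seq, occupancy-plus-background fragments for
ChIP-seq, constant-abundance spike-ins under varying library depth. Every
stage of the analysis is validated by recovering the simulated truth.

## Worked example

Simulate 40 genes at steady state — control elongating at 2 kb/min, a
"depleted" condition at 1 kb/min — and recover the factor-of-two slowdown:

```python
from polvel import (make_genome, KineticsSpec, ConditionSpec, SamplingSpec,
                    emit_dataset, ElongationVelocityModel)
from polvel.quantify import fragment_midpoints, count_features, rpk_and_filter
from polvel.normalize import spikein_size_factors
from polvel.recovery import _pool, _spike_counts

genome = make_genome(n_genes=40, length_min=10_000, length_max=60_000, seed=0)
kinetics = {g.gene_id: KineticsSpec.constant(2.0, 2.0, g.length)
            for g in genome.genes}
conditions = [ConditionSpec("control", velocity_factor=1.0, onset_time=-1e9),
              ConditionSpec("depleted", velocity_factor=0.5, onset_time=-1e9)]
sampling = SamplingSpec(replicates=2, library_scales=[1.0, 1.2, 0.9, 1.1])
ds = emit_dataset(genome, kinetics, conditions, sampling, seed=11,
                  assays=("ttseq", "mnet"))

labeled = [s.spike_id for s in genome.spikeins if s.labeled]
sf_tt = spikein_size_factors(_spike_counts(ds.ttseq, genome.spikeins), labeled)
sf_mn = spikein_size_factors(_spike_counts(ds.mnet, genome.spikeins), labeled)
tt, mn = _pool(ds.ttseq), _pool(ds.mnet)
expressed = rpk_and_filter(count_features(tt, genome.genes).counts, genome.genes)
genes = [g for g in genome.genes if g.gene_id in set(expressed.gene_ids)]

model = ElongationVelocityModel(
    tt_midpoints=fragment_midpoints(tt),
    mnet_tags=mn[mn["end"] - mn["start"] == 1],
    genes=genes, design=ds.samples[["sample", "condition"]],
    sf_tt=sf_tt, sf_mnet=sf_mn, control="control")
print(model.fit().summary())
```

prints

```
Elongation velocity contrast (TT-seq / mNET-seq ratio)
==========================================================
conditions:        depleted vs control
genes analysed:    40 (of 40)
gene-body region:  TSS+1000 bp to TES
median log2 velocity change: -1.0152
one-sample Wilcoxon (mu=0):  W=0.0, p=3.71e-08 [signed_rank_normal, n=40]
log2-change box:   median -1.015, hinges [-1.243, -0.802], notch [-1.125, -0.905]
```

The median log2 velocity change of **−1.02** recovers the simulated
log2(0.5) = −1: despite library depths differing by up to 30%, the
spike-in factors put all four samples on one scale and the TT/mNET ratio
isolates velocity from initiation. W = 0 means every gene's ratio dropped.

## Command-line pipeline

The same analysis runs end to end from a YAML config
(`polvel init-config` prints a template; a bundled smoke config lives at
`src/polvel/data/smoke.yaml`):

```bash
polvel all --config config.yaml --outdir out --seed 7
```

Stages (`simulate`, `quantify`, `normalize`, `velocity`, `metagene`,
`report`) are individually re-runnable from their on-disk intermediates
(BED6, TSV, bedGraph). Outputs carry provenance headers (version, config
hash, seed) and identical (config, seed) reruns are byte-identical.

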