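# nucleofoot

Nucleosome footprinting of cell-free DNA (cfDNA) around transcription
start sites (TSSs).

Plasma cfDNA is released largely as mononucleosome-protected fragments
(~166 bp; MNase-protected cores are ~146 bp). Because transcriptionally
active promoters carry a nucleosome-depleted region (NDR, here −150..+50
bp around the TSS), the local density of cfDNA fragments near a TSS is a
readout of gene activity in the tissues shedding the DNA. `nucleofoot`
is a library + CLI for scientists who want to quantify that footprint
from fragment intervals and use it for cohort comparisons and
classification — without alignment-level machinery: the inputs are
plain BED fragments, a TSS table, and optional TPM expression tables.

## What it computes

* **Occupancy** — per TSS and sample, fragments with midpoint in
  `[tss − 1 kb, tss + 1 kb)` normalized as
  `RPKM = count / ((2·flank/1000) · (total/10⁶))`; per-base NDR depth
  (strand-mirrored window); strand-oriented metagene depth profiles;
  fragment-length summaries.
* **Expression association** — occupancy quartiles (HTSS/LTSS) versus
  expression classes (TPM > 10 / TPM = 0), with overlap significance
  from a permutation null: 1000 resamplings of set membership,
  z-standardized, two-sided normal p; Spearman concordance across
  platforms.
* **Differential TSSs** — per-TSS two-sided Wilcoxon rank-sum between
  two cohorts, pseudocounted fold change of group means, optional
  Benjamini–Hochberg FDR; calls at configurable thresholds (e.g.
  p < 0.01 and |log FC| ≥ log 1.5); average-linkage (UPGMA) clustering
  order for heatmaps.
* **Promoter classifier** — per-feature discretization at the cutoff
  maximizing (sensitivity + specificity)/2 learned on training folds
  only, LASSO-penalized logistic regression (penalty chosen by inner
  CV), stratified five-fold cross-validation repeated 100×, ROC/AUC.
* **Synthetic cohorts** — a simulator producing nucleosome-phased
  fragment midpoints, expression-coupled NDR depletion, assay-specific
  fragment lengths, and two-group cohorts with planted differential
  TSSs, so the whole pipeline runs end-to-end with no external data.

## Worked example

```python
import nucleofoot as nf

cfg = nf.SimulatorConfig(seed=1)          # 2000 genes, 2×5 Mb genome
land = nf.simulate_landscape(cfg)
design = nf.CohortDesign(n_group_a=28, n_group_b=10,
                         n_differential_tss=150, effect_factor=1.8)
sa, sb, truth = nf.simulate_cohort(land, cfg, design)

occ = nf.occupancy_matrix(sa + sb, land.tss)        # 2000 TSS × 38 samples
labels = {fs.sample_id: "resp" for fs in sa}
labels |= {fs.sample_id: "nonresp" for fs in sb}
table = nf.call_differential(occ, labels,
                             nf.AnalysisThresholds(p_max=0.01, fc_min=1.5))
called = table[table["call"] != "ns"]
print(len(called), "differential TSSs;",
      len(set(called.index) & truth.differential_tss_ids), "are planted")
```

prints

```
150 differential TSSs; 150 are planted
```

i.e. at p < 0.01 and fold change ≥ 1.5 the test recovers all 150
planted promoters on this seed with no false positives (across seeds
the average sensitivity is ≈0.97 with a false-discovery proportion
near zero; see the acceptance script). The same objects feed the
classifier:

```python
rep = nf.repeated_cv(occ, labels, n_repeats=20, seed=2,
                     filter_thresholds=nf.AnalysisThresholds(),
                     filter_scope="global")
print(round(rep.median_auc, 3))   # -> 1.0 on this well-separated cohort
```

The same pipeline is available from the shell:

```bash
nucleofoot run-all --out demo --seed 1
```

which writes fragment BEDs, the occupancy matrix, the differential
table with cluster order, the CV report, and a `manifest.json` listing
every artifact with its SHA-256 — rerunning with the same seed
reproduces the manifest byte for byte.

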