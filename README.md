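# splicemark

Junction-read quantification of alternative splicing and biomarker
discovery for paired tumor/normal RNA-seq cohorts — percent-spliced-in
(PSI) statistics, differential-splicing selection, a metastasis-association
filter, TCGA-style junction-usage normalization, a group-constrained
logistic-regression predictor search, and median-split survival
association. Every stage is exercisable end-to-end on seeded synthetic
junction-count data with planted ground truth.

## Who this is for

Analysts studying recurrent splicing changes between tissue groups (e.g.
normal colon vs. primary colorectal tumor vs. liver metastasis) from bulk
RNA-seq, who want the whole chain — from filtered spliced alignments or
STAR `SJ.out.tab` junction counts to candidate splicing biomarkers with
classifier and survival support — as a tested, reproducible library rather
than a pile of one-off scripts.

## The statistics at the core

**Cassette-exon PSI.** For an alternative exon with upstream-junction,
downstream-junction and skip-junction read counts *a*, *b*, *c*:

    PSI_exon = (a + b) / (a + b + 2c)

The skip count is doubled because the inclusion isoform exposes two
junctions where the skipping isoform exposes one. A PSI value is reported
only when a + b + c ≥ 10 (minimum informative reads), otherwise missing.

**Site-sharing junction PSI.** For a junction *j* among all junctions
sharing its 5′ splice site (PSI_junc5′) or 3′ splice site (PSI_junc3′):

    PSI_junc = count(j) / Σ_k count(k),  k over the site group

These handle complex loci (CD44-like multi-exon cassettes) and alternative
first/last exons, where the three-junction formula does not apply.

**Differential splicing.** Two-sided Wilcoxon rank-sum on per-sample PSI;
effect size ΔPSI = mean(group B) − mean(group A); discovery cutoffs
p < 0.05 and |ΔPSI| > 0.20, intersected across cohorts with sign
agreement. Metastasis-associated events additionally require
|ΔPSI(MC−NC)| > 0.20 with p < 0.001, a consistent ΔPSI sign across all
contrasts, and a further shift |mean(MC) − mean(CRC)| ≥ 0.15.

**Junction usage.** usage(j, person) = quant(j, person) / mean over the
gene's junctions of quant(·, person), so per gene and person the mean
usage is exactly 1. Validation contrasts on usage are Bonferroni-adjusted.

**Predictor search.** Eight junction predictors are clustered into 3
groups (average linkage on 1 − Spearman ρ); candidate sets are all
singletons, all {group-1, group-2∪3} pairs, and all one-per-group triples
(41 sets for group sizes 3/2/3). Each set is scored by 5 random 50/50
train/test splits of an unregularized logistic regression, ranked by mean
test AUC; the final model is the top-AUC split of the best set.

**Survival.** Patients are split at the median of a junction's usage
(ties go low); groups are compared by Kaplan–Meier curves and the log-rank
test.

## Worked example

The numbered scripts under `analysis/` run the whole chain on simulated
study-condition data (18 tumor/normal pairs, ~200 informative reads per
event, planted PSI shifts 0.50→0.85 and 0.10→0.45 among 100 null events;
a 382-tumor/51-normal usage matrix in three correlation blocks):

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_differential_splicing.py
```

prints

```
tested 102 events (2 planted, 100 null)
planted events passing the joint filter: 2/2
null events passing: 0/100 (0.00%)
  GENE0000:cassette:chrS:10300-10400: dPSI=+0.335 p=3.22e-07
  GENE0001:cassette:chrS:20300-20400: dPSI=+0.332 p=3.21e-07
```

Both planted effects are recovered near their true ΔPSI = 0.35 and no null
event passes the joint filter. The predictor search
(`analysis/04_predictor_search.py`) then reports

```
evaluated 41 predictor sets; 15 reach mean AUC > 0.99
best set: junc_b1_1+junc_b2_1+junc_b3_1 (mean AUC 1.0000, ...)
```

i.e. the 41-set enumeration with a three-predictor final model that
separates tumors from normals perfectly on held-out halves, and
`analysis/05_survival_association.py` shows the hazard-driving junction
with a log-rank χ² of 75.9 (p ≈ 3×10⁻¹⁸) while junctions in unrelated
correlation blocks stay at chance.

The same stages are available from the shell via the `splicemark` CLI
(`count`, `psi`, `diff`, `classify`, `survival`, `simulate`, `run`).

## Layout

- `src/splicemark/` — the library: `annotation` (gene models, event
  catalog), `counting` (read filter, junction/exon counts, SJ/BED12/SAM
  dialects), `psi`, `diffsplice`, `classifier`, `survival`, `simulate`
  (seeded generators with planted truth), `pipeline` + `cli`.
- `analysis/` — numbered narrative drivers writing tables to `results/`.
- `docs/methods.md` — models, assumptions, parameter defaults, numerical
  choices and limitations.
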