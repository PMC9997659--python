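# djsplice

Junction-level differential splicing analysis for discovering and
characterizing unannotated cassette exons — with companion tools for
percent-spliced-in (PSI) quantification, trait association, in-silico
RT-PCR isoform validation, and magnetic-tweezers force-ramp unfolding
analysis. Everything runs on seeded synthetic cohorts that emulate the
structure of tumor/normal RNA-seq junction-count data, so the whole
pipeline is exercisable (and testable) on a laptop.

The motivating use case is the kind of discovery where a gene long
assumed to have a single isoform — e.g. talin-1, the mechanosensitive
integrin adapter — turns out to harbor a short, in-frame cassette exon
visible only at the splice-junction level: two *non-annotated* inclusion
junctions go up while the annotated exon-skipping junction goes down,
the inserted peptide shifts an RT-PCR amplicon by the exon length, and
the insertion changes the forces at which the protein's rod domains
unfold under a force ramp.

## What it computes

**Differential junction expression (DJE).** Junction read counts
(STAR `SJ.out.tab` or a merged junction×sample TSV) are gene-annotated
against a GTF, filtered (mean count ≥ 10), and transformed to
log₂ counts-per-million. Observation-level precision weights come from a
lowess mean–variance trend (weight = predicted √sd⁻⁴). A weighted
two-group linear model per junction yields

- `logFC_abs` — change of the junction's own normalized expression, and
- `logFC_rel` — junction *usage*: its logFC minus the mean logFC of the
  gene's other retained junctions,

both tested with empirical-Bayes moderated t-statistics: residual
variances are shrunk as s²ₚₒₛₜ = (d₀s₀² + d·s²)/(d₀ + d) with the prior
(d₀, s₀²) estimated by method-of-moments on log s² (verified against
Bioconductor limma's `eBayes` to machine precision). Junctions are
called up/down when |logFC_abs| exceeds the cutoff (default 1.0) and
both Benjamini–Hochberg FDRs fall below α = 0.05.

**Cassette events and PSI.** Junction trios (two inclusion flanks + one
skipping junction spanning them) define cassette events;
ψ̂ = mean(c_inc1, c_inc2)/(mean(c_inc1, c_inc2) + c_skip) ∈ [0, 1], missing
below 10 supporting reads. Cross-event Pearson correlation (BH-adjusted
across pairs) detects trans-mutually exclusive splicing.

**Trait association.** Biweight midcorrelation (bicor, tuning constant
9) of junction/event profiles against continuous traits such as drug
AUC or CRISPR gene-effect scores, with t-approximation p-values, BH
FDR, |rho| ranking, a radar-chart export (FDR < 0.05, |rho| > 0.2,
axis −0.5..0.5), and hypergeometric gene-set over-representation.

**In-silico RT-PCR.** Exact primer matching on both strands, amplicon
sizing on inclusion vs skipping templates, in-frame insert translation,
and genomic-interval arithmetic.

**Force spectroscopy.** Bead-height traces under a linear force ramp
F(t) = f_start + r·t (or a calibrated magnet law F(d(t))) are segmented
by penalized binary-segmentation change-point search; positive steps
≥ 10 nm become unfolding events with forces read off the schedule, and
ensembles are summarized as density-normalized unfolding-force
histograms with per-band modal forces. The bundled simulator draws
unfolding forces from Bell–Evans kinetics, k(F) = k₀·exp(F·Δx/k_BT).

## Worked example

```bash
djsplice all --seed 7 --outdir run7
```

simulates a 60 + 60 sample cohort (10 genes, 6 junctions each) in which
`gene_1` carries a hidden 51-nt cassette exon with inclusion fraction
0.7 in group A vs 0.05 in group B, then runs annotation → filtering →
DJE → events/PSI → trait association, logging
`pipeline complete: 12 artifacts in run7`. The only significant
junctions in `run7/dje_results.tsv` are exactly the cassette trio:

```
junction        gene_id  status          logFC_abs  class
chrS:701-900:-  gene_1   annotated           -1.67  down
chrS:701-774:-  gene_1   novel_donor          3.83  up
chrS:826-900:-  gene_1   novel_acceptor       3.83  up
```

i.e. the two non-annotated inclusion junctions come up
(+3.83 ≈ log₂(0.7/0.05)) and the annotated skipping junction comes down
(−1.67 ≈ log₂(0.3/0.95)); `run7/spliceplots.json` colors them red/blue
with everything else black. `run7/psi.tsv` holds the detected event's
per-sample PSI (group means 0.69 and 0.05, recovering the programmed
0.7/0.05), and `run7/trait_associations.tsv` ranks the simulated
AUC-like trait's correlations, led by the inclusion features at
rho ≈ −0.97. Re-running with the same seed reproduces every data
artifact byte-for-byte.

The same operations are importable directly:

```python
from djsplice import (CohortSpec, simulate_cohort, annotate_junctions,
                      filter_junctions, fit_dje)
table, annotation, truth = simulate_cohort(CohortSpec(seed=7))
statuses = annotate_junctions(table, annotation)
result = fit_dje(filter_junctions(table),
                 ["A"] * 60 + ["B"] * 60, statuses)
print(result.table[result.table["class"] != "ns"])
```

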