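# Methods

This note documents the models, estimators and design choices behind
djsplice, what the synthetic generators do and do not emulate, and the
numerical conventions used throughout.

## Junction representation and annotation

Junctions are keyed by the 1-based inclusive first and last base of the
excised intron (the STAR `SJ.out.tab` convention), so a junction joining
an exon ending at p to an exon starting at q is `(p+1, q-1)`. All
exports state this convention in their headers.

A junction is assigned to the gene whose span contains both splice
sites; among multiple candidates we prefer a strand match, then the
smallest genomic span, and leave the remainder unassigned — a
deterministic, conservative rule. Novelty classes are computed against
the union of annotated exon boundaries: `annotated` requires both sites
*and* their pairing to occur in some transcript; `novel_combination`
means both sites are known but never paired; `novel_donor` /
`novel_acceptor` name the missing site strand-awarely (the donor is the
transcription-upstream site, so on reverse-strand genes the donor sits
at the right-hand genomic flank); `novel_both` means neither site is
annotated. Transcript-order indices number a gene's observed junctions
along the direction of transcription (reverse-strand genes right to
left), which is what the splice-plot x-axis uses.

## Differential junction expression

**Normalization.** logCPM = log₂((count + 0.5)/(library size + 1)·10⁶).
The +0.5/+1 offsets are the standard limma-voom convention; library
sizes are total mapped reads, which the simulator draws uniformly from
the configured range.

**Precision weights.** Junction counts are overdispersed, and the
variance of logCPM falls with expression. We fit an unweighted
two-group model per junction, lowess-smooth √(residual sd) against mean
logCPM (span 0.5), evaluate the trend at each observation's fitted
logCPM (constant extrapolation beyond the trend range), and set the
observation weight to the predicted √sd⁻⁴ — an inverse-variance weight.
With fewer than five junctions the trend is degenerate and unit weights
are used.

**Moderated statistics.** Per junction a weighted least-squares fit on
the design [1, group] gives the absolute logFC (the first-appearing
group level is the condition of interest, the second the reference).
Residual variances s² on d = n−2 df are shrunk toward a prior:
s²ₚₒₛₜ = (d₀s₀² + d·s²)/(d₀ + d), with (d₀, s₀²) estimated by moment
matching on log s² (digamma/trigamma corrections, trigamma-inverse by
Newton iteration); d₀ is capped at 10⁶ as a finite stand-in for an
infinite prior. Moderated t = logFC/(u·sₚₒₛₜ) is referred to a
t-distribution on d₀ + d df (capped at the pooled residual df). The
implementation agrees with Bioconductor limma's `lmFit` + `eBayes` to
~1e-14 on shared inputs, which a test enforces through an independent
Rscript route.

**Relative logFC (usage).** The paper-level notion of a junction's
*usage* change is implemented as a diffSplice-style contrast: the
junction's logFC minus the mean logFC of the gene's other retained
junctions. Its squared standard error is the junction's moderated
variance plus 1/m² times the sum of the others' (independence
approximation across junction fits). Genes with a single retained
junction are flagged and excluded from relative testing. This definition
is an interpretation — the source figures distinguish "absolute or
relative logFC" without printing formulas — and is stated prominently
here for that reason.

**Calling.** Absolute and relative p-values are BH-adjusted separately;
a junction is `up` (`down`) only when logFC_abs > cutoff (< −cutoff)
*and both* FDRs are below α. Reading the figure-legend wording "FDR >
0.05 for absolute or relative logFC (or both) are shown in black" as a
conjunction requirement for significance is a deliberate choice.
Defaults: cutoff 1.0 (tumor-vs-normal-style contrasts; 0.5 is the
convention for condition contrasts), α = 0.05, filter min mean 10.
Two-group designs only; multi-factor designs are out of scope.

## Cassette events and PSI

A cassette event is a trio (J_inc1, J_inc2, J_skip) with
J_skip.intron = [J_inc1.start, J_inc2.end] and the cassette strictly
inside; trios are enumerated per gene, so events with non-annotated
flanks and an annotated skipping junction — the signature of a missing
exon — are found naturally.

PSI uses the **mean** of the two inclusion junctions, not their sum:
ψ̂ = mean(c₁, c₂)/(mean(c₁, c₂) + c_skip). With both flanks at equal
expected depth A·ψ and the skipping junction at A·(1−ψ), the estimator
is unbiased for ψ; summing the flanks would double-weight inclusion.
ψ̂ is missing when the denominator is below `min_cov` (default 10,
mirroring the junction filter). Junction reads only are used — exon-body
reads are not consulted. Cross-event correlation is Pearson on
pairwise-complete samples with BH adjustment across all tested pairs;
constant vectors are flagged degenerate rather than imputed.

## Trait association

bicor follows the standard definition: values are centred at the
median, scaled by 9·MAD, and weighted by Tukey biweights (1−u²)² for
|u| < 1. A zero-MAD vector has no defined biweight standardization, so
the implementation falls back to Pearson with a warning. P-values use
the t-approximation t = rho·√((n−2)/(1−rho²)) on n−2 df — the source
states only the α, and this is standard bicor practice. Missing data
are handled pairwise-complete with n_used recorded per pair. The radar
export keeps FDR < α and |rho| > 0.2 and clips to the −0.5..0.5 radial
axis. Over-representation of ranked correlates is a set-agnostic
hypergeometric tail test with BH adjustment — a deliberate divergence
from database-backed KEGG enrichment, which would require external
retrieval; preranked running-sum GSEA is intentionally not implemented.

## In-silico RT-PCR

Primer matching is exact (no mismatch model): the short, specific
primers used for cassette-exon genotyping at stringent annealing make
mismatch tolerance unnecessary, and exactness keeps product sets
deterministic. Every (forward sense-match, reverse antisense-match)
pair with the forward site upstream yields a product up to a 5 kb cap,
mirroring multi-band gels rather than erroring on multiple binding
sites. Insert translation works at the protein level: both CDSs are
translated and the inserted residues located by prefix/suffix
comparison, so an insert is accepted wherever it leaves the flanking
residues intact; non-multiple-of-3 inserts raise a frameshift error and
in-frame stops are flagged. Thermal-cycle parameters are metadata only.

## Force-ramp analysis

**Simulator.** Force rises linearly from f_start at rate r (defaults
1 pN/s from f_start = 1 pN, 200 Hz sampling, 1 nm Gaussian height
noise, f_max ≤ 100 pN — the working range and resolution of
magnetic-tweezers instruments this emulates). Each domain unfolds once
at a force sampled by inverting the Bell–Evans ramp survival function
S(F) = exp(−(k₀ k_BT)/(r·Δx)·(e^{FΔx/k_BT} − e^{f_startΔx/k_BT}));
Bell–Evans is the minimal standard kinetic model and admits the
closed-form modal force F* = (k_BT/Δx)·ln(rΔx/(k₀k_BT)) used as an
oracle in tests. The default three-domain construct places modes near
5, 15 and 25 pN with 22–28 nm steps (rod-domain-like magnitudes, Δx of
2–5 nm and physically plausible k₀). Domains whose sampled force
exceeds f_max stay folded and are marked unresolved. Refolding within a
scan is not simulated — one unfolding per domain per scan, matching
per-scan histogramming practice.

**Detector.** Since no published step-calling criteria exist for these
traces, the detector is the package's own: penalized binary
segmentation under a piecewise-constant SSE cost, with the noise scale
σ estimated robustly from first differences (MAD/(0.6745·√2)) and
penalty 10σ²·ln n (floored at 1e-6 so numerically flat noise-free
traces do not fragment). Adjacent-segment mean jumps ≥ min_step
(default 10 nm — half the >20 nm rod-domain step scale, rejecting noise
while keeping sensitivity) become events, time-stamped at the midpoint
of the bounding samples, giving a worst-case force quantization of half
a sample interval × r (0.0025 pN at defaults). Drift correction is not
applied; the piecewise-constant model tolerates mild drift.

**Histograms.** Density-normalized with configurable bin width; modal
forces per user-configured force band are located by KDE argmax
(bin-center fallback below five events), and domain assignment by force
bands rather than unsupervised clustering keeps the summary
deterministic.

## Synthetic cohort generator

The generator emulates the *structure* of two-group junction-count
cohorts: per gene a linear chain of 100-nt exons and 200-nt introns
(junctions per gene configurable, ≥ 2); cassette genes carry a hidden
51-nt exon centred in the middle intron, with the two inclusion
junctions withheld from the emitted GTF. Expected counts are gene
abundance × isoform usage (inclusion paths ψ·A each, skipping path
(1−ψ)·A; constitutive junctions A), scaled by library size over the
range midpoint, and drawn negative-binomial with shared dispersion
(var = μ + φμ², φ = 0.05 by default; φ = 0 gives Poisson). NB is an
assumption — no noise model for cohort junction counts is established —
chosen because it produces the overdispersion that voom-style weights
are designed for. Default study conditions: 60 + 60 samples, abundance
100 reads/junction, library sizes uniform in [0.8M, 1.2M], cassette
inclusion 0.7 vs 0.05. `psi_profiles` can override group-level ψ with
per-sample values to program anti-coupled event pairs or trait-linked
inclusion.

What the generator does **not** emulate: read-level artifacts
(mapping bias, positional coverage, multi-mapping), sample quality
variation, batch effects, correlated junction noise within a gene,
isoform complexity beyond one cassette per gene, or real annotation
messiness (overlapping genes, many transcripts). Passing tests
demonstrate the pipeline's correctness under its stated model, not
robustness to those real-data complications.

## Pipeline and provenance

`run_pipeline` chains simulate → annotate → filter → DJE → events/PSI →
traits and writes TSV/JSON artifacts plus `provenance.json` (package
version, timestamp, SHA-256 of the canonical sorted-key config JSON —
stable under key reordering). Data artifacts are byte-identical across
re-runs with the same config; the timestamp lives only in the
provenance file, which is excluded from that guarantee. The trait stage
generates one AUC-like trait coupled to the first cassette gene's true
inclusion (coupling −3, noise sd 0.1) plus unit-variance noise traits.
The CLI is a thin shell over these library calls (exit 0 on success, 2
on validation errors).

## Problem sizes in the test suite

Simulation-backed tests use 10–50 genes, 8–120 samples, 100–500
force-ramp scans and 200–500 Monte-Carlo repeats — sizes chosen so each
statistical check has comfortable margin (e.g. binomial slack on type-I
fractions, <10% mode-recovery error) while the whole suite runs in
seconds.

## Known limitations

- Two-group contrasts only; no covariates or multi-factor designs.
- The relative-logFC contrast and the conjunction significance rule are
  interpretations of figure-legend wording, stated above.
- PSI ignores exon-body reads and non-cassette event classes
  (mutually-exclusive exons, intron retention, alt 5'/3' sites).
- Exact primer matching only; no melting-temperature model.
- The step detector assumes piecewise-constant height; strong
  within-segment drift or refolding cycles would need a different model.
- Junctions spanning two genes are assigned to at most one
  (strand/span tie-break) — never to both.
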