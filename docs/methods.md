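# Methods

This note documents the models and procedures implemented in `mircover`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic generators do and do not emulate.

## Consensus evidence scoring

An evidence table holds one record per (miRNA, gene, source) assertion
with a source class (`validated` for empirically supported databases,
`predicted` for computational tools), a direction (`positive`/`negative`)
and a confidence in [0, 1] (defaulting to 1.0 when the exporting tool
provides none). Identifiers are compared case-insensitively because
public resources mix capitalisation; duplicate (miRNA, gene, source) keys
are an error rather than silently deduplicated, so tallies are
reproducible from the file alone. Records for genes outside the candidate
set are ignored, not rejected — evidence exports typically cover the
whole genome.

The validated and predicted scores count genes of the candidate set with
at least one record of that class, making them simultaneous-coverage
statistics rather than record counts. Positive/negative evidence counts
validated records (not distinct experiments — record-level counting is
the only option that is well defined for arbitrary exports), and
net = positive − negative. The number of distinct sources is counted per
miRNA across all candidate genes.

The **integrated score** Σ_g max_s c(m,g,s) is this package's own
aggregate. Consensus databases publish integrated confidence values whose
formulas depend on their private score inputs and are not reproducible
from the outside; the sum-of-best-confidence surrogate keeps the intended
semantics (more genes and better per-gene support ⇒ higher score), is
bounded by the gene-set size, and is order-compatible with coverage.
Published integrated-score values are therefore treated as data to carry
through, never as numbers this package should reproduce.

Ranking filters on coverage counting either evidence class (consensus
searches pool validated and predicted hits before asking which miRNAs
target multiple genes), then sorts by (validated score, predicted score,
net evidence, integrated score) descending. The hierarchy puts empirical
coverage first — the field's convention when validated and predicted
evidence disagree — and the final lexicographic miRNA-id tie-break makes
the order total, so reruns and row permutations give identical output.

## Seed sites, duplex alignment, free energy

The seed is defined as miRNA nucleotides 2–8 from the 5′ end and sites are
classified into the canonical taxonomy: 8mer (positions 2–8 paired plus an
A opposite position 1), 7mer-m8, 7mer-A1, 6mer. Matching within the seed
is strict Watson–Crick; G:U wobble is accepted only in the
3′-supplementary region. One site is reported per occurrence of the
seed core (reverse complement of positions 2–7), labelled with the most
specific class its flanks support; this avoids double-reporting the
6mer/7mer windows nested inside every 8mer while still reporting all
overlapping core occurrences. Coordinates are 0-based half-open on the UTR
sense strand.

The supplementary alignment is a global affine-gap alignment (Gotoh) of
the miRNA, displayed 3′→5′, against the UTR window read 5′→3′, scored
+5 for Watson–Crick columns, +1 for G:U, −3 for mismatches, −8 gap open
and −2 gap extend — complementarity-alignment values in the tradition of
seed-anchored target scanners. Traceback ties are broken deterministically
(pair column, then gap in the miRNA row, then gap in the UTR row), so
alignments are bit-reproducible. The window for a site extends 5′-ward on
the UTR by the miRNA length minus the site length, giving the 3′ region
room to pair.

Hybridization ΔG (kcal/mol, 37 °C) is an additive nearest-neighbor sum
over stacked pairs using the 16-entry Watson–Crick stacking table shipped
in `src/mircover/data/rna_stack_params.tsv`, plus a duplex initiation
penalty, a flat term for stacks involving a wobble pair, and a linear
penalty `loop_open + loop_per_nt × n` for each internal run of n unpaired
nucleotides; dangling ends are free. The initiation penalty is set to
+0.5 kcal/mol — deliberately smaller than calorimetric duplex-initiation
values — so that any duplex with at least two stacked Watson–Crick pairs
has ΔG ≤ 0 (the weakest stack contributes −0.93). The scale is thus a
reproducible surrogate: site rankings and helix-extension monotonicity
are meaningful, absolute agreement with folding programs is a non-goal.
An alignment with no paired columns reports the bare initiation penalty
and is flagged non-binding.

## Over-representation analysis

The statistic is the exact hypergeometric upper tail
P[X ≥ k], X ~ Hypergeom(N, K, n), for k query genes of n in a term of K
genes within a universe of N, computed by log-space summation of point
masses (gammaln + logsumexp) so small p-values are stable. The test is
one-sided (over-representation only). The universe defaults to the union
of all annotated genes, the behaviour of common enrichment servers;
query genes outside the universe are an error that lists the offenders.
Benjamini–Hochberg adjustment is the classical step-up rule with the
cumulative minimum applied from the largest rank; input order is restored
on return. The default significance rule is FDR < 0.05. Servers that use
a modified Fisher (EASE-style) score will report different numbers for
the same input; this implementation is exact hypergeometric by design.

## Relative expression (2^−ΔΔCt)

Per replicate, ΔCt = Ct(target) − Ct(reference) within the same sample;
ΔΔCt = ΔCt(treated) − mean ΔCt(control); fold change = 2^−ΔΔCt.
Design choices:

* the control baseline is the mean control ΔCt (unpaired wells), not a
  per-replicate pairing;
* replicate fold changes are aggregated by the geometric mean, since fold
  changes are ratios;
* group testing is done on the ΔCt scale with classical one-way ANOVA and
  Tukey HSD from the studentized-range distribution (for two groups the
  Tukey p-value equals the ANOVA p-value exactly, since q = √2·|t|);
* significance is called at p < 0.05 per assay without multiplicity
  adjustment across assays — mirroring common qPCR practice — with an
  optional BH adjustment (`--fdr`) as a documented deviation;
* normality screening uses the plain one-sample Kolmogorov–Smirnov test
  against a normal with the sample mean and SD and the asymptotic
  p-value. Because the parameters are estimated from the same data, the
  p-value is conservative (the Lilliefors correction is deliberately not
  applied; this matches the default KS dialog of common statistics
  packages and is documented as such).

Amplification-efficiency correction and standard curves are out of scope.

## Cell-cycle deconvolution

DNA-content histograms are modelled as a three-component mixture: G1
~ Normal(μ1, cv·μ1), G2/M ~ Normal(μ2, cv·μ2) with μ2 constrained to
2·μ1 within ±15% (4N ≈ 2×2N), and S uniform on [μ1, μ2]. The shared
coefficient of variation reflects stain noise scaling with intensity.
S-phase cells are thus "events between the peaks not attributed to either
Gaussian", attributed by posterior probability rather than a hard
±2σ window: a hard window systematically misses the S events lying under
the peaks (about 30% of them at cv = 0.05) and would bias S down by
several points, while the posterior attribution recovers the planted
fractions to well within ±0.03 at n = 10 000.

Fitting is a safeguarded generalized EM from a histogram-mode
initialisation (the G1 peak is disambiguated from the 4N peak by
comparing event mass at half and at twice the mode): the mixture-weight
update is always applied — for fixed component densities it cannot
decrease the likelihood — and the joint (μ1, ratio, cv) update is
accepted only when the log-likelihood does not drop, so the trace is
monotone by construction (asserted in tests). Tolerance 1e-8, at most 500
iterations; the fit is fully deterministic. Debris and doublets are
removed by one trim-and-refit pass dropping events outside
[0.3·μ1, 1.3·μ2]. Unimodal input (no resolvable 4N peak, or
zero-variance data) is reported with G2/M = 0 and a `degenerate` flag.
Fractions are renormalised to sum to exactly 1. The fit is invariant
under multiplicative intensity rescaling.

Condition comparisons run a per-phase one-way ANOVA (+ Tukey) across
replicate fraction estimates, requiring ≥3 replicates per condition.
Input is plain CSV of per-cell intensities; FCS parsing is an extension
point, not part of the analysis.

## Synthetic generators

All generators draw from `numpy.random.default_rng` (PCG64) seeded by
`SimulationConfig.seed` plus a fixed per-generator stream constant, so
outputs are bit-reproducible and the streams are independent. Every
generator returns machine-readable truth for closed-loop tests. Defaults
are chosen to mirror the intended study conditions:

* **Evidence**: a six-gene candidate set, 50 miRNAs of which three are
  hubs shaped like the strongest real candidates (e.g. 16 validated
  records over 6 genes with 1 negative ⇒ net 14), distributed
  round-robin over genes and sources so the planted tallies are exact;
  background miRNAs get at most one covered gene. Confidences are
  uniform on [0.5, 1].
* **UTRs**: 22-nt random miRNAs and 500-nt random UTRs with one site per
  canonical class planted at recorded, non-overlapping offsets; guard
  bases force each planted site to classify as exactly its intended type.
  Chance background sites can still occur and are not listed as truth.
* **Ct tables**: 3 treated + 3 control samples; target Ct 24, reference
  Ct 16, per-well noise σ = 0.15 cycles, per-sample loading offsets
  (SD 0.3 cycles) that reference normalisation must cancel; a planted
  fold change f shifts treated target Ct by −log2 f (default 0.4 across
  all six assays).
* **PI intensities**: multinomial phase counts at fractions
  0.60/0.25/0.15, G1 peak μ1 = 100, cv = 0.05, n = 10 000; S events are
  uniform DNA content between the peaks with multiplicative noise of the
  same cv.

What the generators do **not** emulate: realistic miRNA/UTR base
composition and conservation structure, database-specific score
distributions and redundancy, qPCR efficiency drift and melt-curve
artefacts, debris/aggregate populations and apoptotic sub-G1 cells.
Passing recovery tests therefore demonstrates correctness of the
estimators under their stated models, not robustness to every artefact of
real exports or cytometry data.

## Problem sizes and numerical conventions

Oracle-agreement suites run 200 random instances per check (evidence
tables up to 10 miRNAs × 6 genes × 12 sources; 22-nt miRNAs against
500-nt UTRs; alignment windows up to 40 nt); the enumeration check for
the hypergeometric tail covers random configurations with universes up to
60 at 1e-10 tolerance; ΔΔCt recovery uses 1000 simulations and the null
calibration 2000; cell-cycle recovery is checked at n = 10 000 events.
Ties are broken deterministically everywhere (documented per module);
p-values are clipped to [0, 1]; the evidence confidence bound, enum
values and table keys are validated on read with errors naming the
offending line.

## Known limitations

* The integrated score is a surrogate; it is not comparable in value to
  any external database's integrated score.
* ΔG values are on a reduced surrogate scale (see above) and should only
  be compared within runs of this package.
* The exact hypergeometric p-values will not match servers using EASE
  scores, and no GO-graph propagation is performed.
* The KS normality p-value is conservative for estimated parameters.
* Cell-cycle fitting assumes a single cycling population; aneuploid
  mixtures and sub-G1 quantification are out of scope.
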