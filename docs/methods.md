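# Methods

## Problem setting

The package operates on the two-step logic of core-TRN identification:
first assemble a broad candidate set of core transcription factors for a
target cell type by combining transcript-level evidence with literature
evidence, then resolve the hierarchy among the candidates with a
perturbation (single-factor over-expression) screen. A third group of
routines quantifies how far a reconstructed (factor-transduced) profile
has moved toward the target cell type, at the gene level and at the
level of promoter-motif activities.

## Core-element selection

**Quantile normalization.** All samples of both cell types are normalized
together: each column's sorted values are replaced by the across-column
mean at the same rank, so all columns share one empirical distribution.
Ties are resolved by stable sort order, which makes the transform
idempotent to machine precision. Row order is preserved.

**Detection filter.** A probe is kept when its detection p-value is below
0.01 in at least one sample; this removes probes never expressed above
bead-array background. The filter direction is "keep detected": dropping
detected probes would discard every expressed gene and defeat the
filter's purpose.

**Differential statistics.** Fold change is the ratio of linear group
means, floored at 1.0 signal units (bead-array background is tens of
units, so the floor only guards true zeros). The p-value comes from a
two-sided two-sample t-test on log2 signal; Welch's unequal-variance form
is the default because bead-array variance is heteroskedastic, with a
Student's (pooled) switch available. Welch is slightly conservative at
n = 3 per group (empirical type-I error ≈ 0.034 at α = 0.05) and close to
nominal from n = 5; the null-calibration test uses 5 replicates per group
for that reason. No multiplicity adjustment is applied — ranks, not
significance calls, feed the downstream score.

**Ranking.** TF probes passing fold ≥ 2 and p ≤ 0.05 are ranked by
descending fold change with *competition* (minimum) ranks: tied values
share the smallest rank of the group. TF probes failing the gate share
the sentinel rank `n_passing + 1`. The same convention applies to
literature counts, where it reproduces the characteristic deep shared
rank of the many TFs never co-mentioned with the cell term
(`rank = n_nonzero + 1`).

**Literature mining.** Abstracts are lower-cased token sequences; no NLP
stack, because the method is plain co-occurrence counting. An abstract
passes the keyword filter when it contains at least one of
"differentiation", "development", "transformation" (configurable). A TF's
count is the number of passing abstracts containing both the cell-type
term and any of the TF's names; matching is case-insensitive whole-token
with an optional plural "s" (so "monocyte" matches "monocytes"), and each
abstract contributes at most once per TF.

**Importance score.** `IS = 1/Rfc + 1/Rco`, in (0, 2]. Full precision is
kept internally; 3 decimals are used for display. Selection takes the
top-K records (default K = 20) with boundary ties broken by lower Rfc,
then lower Rco, then probe identifier — a fixed convention so selection
is invariant to input order. Multiple probes of one gene are ranked as
probes; an optional flag collapses to the best probe per gene at
selection time.

## Perturbation hierarchy

qRT-PCR quantities use `2^-ddCt` relative quantification against a
housekeeping gene and a calibrator sample. The perturbation matrix entry
(i, j) is the replicate mean of element i's quantity under transduction
of j, divided by i's quantity in the reference (target) cell type. An
edge j→i requires the entry to *strictly* exceed the edge threshold
(default 0.05, i.e. 5% of the target-cell level) and, by default, to
exceed the mock-transduction baseline of i — an element constitutively
high in mock cells should not generate edges. Self-edges are excluded:
the exogenous transcript cannot count as induction of its own endogenous
locus. Elements measured but never transduced can be edge targets but
not sources, and are excluded from the top-line set by default because
the screen cannot reveal their upstream position. Top-line inducers are
the zero-in-degree nodes; out-degree ranks elements by the breadth of
induction.

## Reconstruction metrics

Target-specific genes are probes with fold ≥ 2 and p < 0.03 in target vs
source; source-specific symmetrically. Regulation calls versus mock use
fold ≥ 2 (or ≤ 1/2) with p < 0.05; the Up/Down/NC categories partition
the probe set. Coverage is the percentage of the target signature called
Up (induced) and of the source signature called Down (repressed). The
fold threshold for coverage defaults to 2; a 4-fold (2²) variant is
reachable through configuration.

Category shifts are tested with the two-sided Wilcoxon rank-sum test on
target-cell expression (Up vs NC, Down vs NC, Up vs Down); paired shifts
(multi-factor vs single-factor fold changes over a target-gene set) use
the Wilcoxon signed-rank test with zero differences dropped. Both use
exact null distributions up to n = 25 (tie-free case) and the normal
approximation with continuity and tie correction above; at least six
pairs are required for the signed-rank test, below which its exact
two-sided p cannot reach 0.05.

Gene-set enrichment is a local two-sided Fisher exact test of the 2×2
table (in/out of study set × in/out of term, within the supplied
universe), through `scipy.stats.fisher_exact`; the test suite verifies
agreement with an exact integer hypergeometric enumeration to 1e-10 over
every table with all margins ≤ 30. Raw p-values are reported
(Benjamini–Hochberg is left to the caller), matching the practice of
reporting unadjusted Fisher p-values for ontology tables.

## Motif activities

**Scanning.** For each promoter window (−300..+100 around the transcript
5′ end, half-open, ≤ 400 bp) and each position-count matrix (pseudocount
0.5 per cell, then row-normalized), every offset on both strands receives
the posterior probability of a site,
`post = π·L_pwm / (π·L_pwm + (1−π)·L_bg)`, with site prior π = 1e-5 and a
0-order background (uniform by default, or estimated from the supplied
promoters). The expected site count `N[p,m]` is the sum of posteriors.
This is the single-species core of posterior-odds site scanning; no
phylogenetic averaging is performed. `N` positions contribute the same
(unknown) background factor to both likelihoods, which cancels, so an
all-N window scores exactly the prior per offset. Windows shorter than
the matrix return 0 with a warning.

**Fitting.** Log2 expression is modeled as
`e[p,s] = c_p + Σ_m N[p,m]·A[m,s] + ε`. Per-promoter intercepts are
removed by centering each promoter's expression across samples; a
per-sample offset is absorbed by centering expression and the site-count
columns across promoters. Each sample's activities solve the ridge system
`(MᵀM + λI)A = Mᵀe` on the doubly centered data; at λ = 0 a
pseudo-inverse is used. Fitted activities are centered per motif across
samples (`Σ_s A[m,s] = 0`), the standard identifiability constraint.
λ defaults to generalized cross-validation over a log-spaced grid
(SVD-based), with a fixed-λ override. Site-count columns with zero
variance across promoters get activity 0 with a warning. Condition
comparisons (e.g. multi-factor vs single-factor transduction) should fit
all samples jointly and compare per-replicate activities of a motif with
the provided Welch t-test helper.

## Synthetic data

The generators emulate the study design, not the platform: two cell
types × 3 replicates; log2-scale signal with Gaussian replicate noise
(sd 0.25 by default) exponentiated to linear intensity, baseline log2
means uniform on [6, 11]; the planted core TFs (8 of 60 by default) are
elevated by 2 log2 units (4-fold) in the target type; ~5% of peripheral
probes are left undetected to exercise the detection filter. Corpus
abstracts always contain the cell term and mention each TF independently
at its planted rate (0.3 core / 0.05 background), with a process keyword
present at rate 0.8 — so a TF's count over passing abstracts is binomial
at its planted rate. Perturbation responses follow a planted DAG: a
responder reachable from the transduced element (direct edges plus,
by default, one transitive step — whether measured induction reflects
cascades is an assumption, not an inference) sits at relative expression
0.30, everything else at the 0.01 background, with log-scale noise
(sd 0.1) that cannot cross the 0.05 edge threshold at realistic draws.
Promoters are uniform-random sequences with planted motif instances at
small Poisson counts; planted instances are high-affinity (consensus with
one PWM-sampled position), representing functional binding sites —
raw PWM samples would make per-site detectability vary by orders of
magnitude at prior 1e-5 and is not what a planted-site benchmark should
measure. Activities are Gaussian (sd 1.0), centered per motif, and
expression follows the linear model with noise sd 0.1.

Each sub-generator draws from `default_rng(master_seed + fixed_offset)`,
so adding one generator to a script never changes another's output.

What passing tests on these data do **not** show: robustness to probe
cross-hybridization, batch effects, non-Gaussian heavy-tailed microarray
noise, real MEDLINE language (synonymy/ambiguity of gene names), feedback
loops or cycles in the real network, or chromatin effects that decouple
binding sites from expression. The synthetic corpus has no entity
ambiguity, so mining performance here is an upper bound.

## Numerical choices and degenerate inputs

- Fold changes floor both group means at 1.0 linear units; probes with
  both groups at zero get fold 1 and p 1.
- Zero-variance t-tests (identical values in both groups) report p = 1.
- All ranks are integers ≥ 1; the importance score rejects anything else.
- Empty corpora, empty keyword lists and edgeless graphs are valid inputs
  with defined outputs (all-zero counts, empty corpus, all-top-line).
- Identical-profile activity comparisons report difference 0, p = 1.
- Problem sizes in the test suite are chosen to finish on one CPU in
  minutes: 50 promoters × 5 motifs for activity recovery, 1000
  simulated datasets for null calibrations, margins ≤ 30 for the
  exhaustive Fisher cross-check.

## Known limitations

- The perturbation stage resolves hierarchy only down to zero-in-degree
  detection; cycles (e.g. auto-regulatory loops) are not resolved.
- The motif scanner is single-sequence; no conservation information.
- The published motif-activity magnitudes are not reproducible without
  the original array data and the exact PWM snapshot, so only model-level
  recovery properties are asserted.
- The literature arm depends entirely on the supplied synonym table;
  no disambiguation is attempted.
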