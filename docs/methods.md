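# Methods

## The model

A HYP is a signed bipartite relation: one upstream biological entity and
the N downstream measurable genes it regulates, each with a sign s_i ∈
{+1, −1}.  Scoring assumes the per-gene log2 differential expressions β_i
are independent estimators, approximately normal with known standard error
sd_i and df_i degrees of freedom (the output of a moderated-t differential
expression fit), and that the contributions of genes irrelevant to the
perturbation average to zero.  All scores are antisymmetric: reversing the
contrast (β → −β, treated ↔ control) or flipping every HYP sign negates
the score exactly, which the test suite checks bit-for-bit.

### Aggregating a network into one HYP

A causal network model is a signed directed graph of entities, some
carrying HYPs.  Signs are propagated from a designated reference node
treating every edge as an undirected constraint sign(target) =
sign(source) × edge sign — a reference node need not be a graph source for
the constraint to be meaningful, so traversal ignores edge orientation.  A
node that would receive both signs (an odd-signed, i.e. negative-feedback,
cycle) is a hard error naming the offending node: resolution is a
biological modelling decision, deliberately not automated here.  A
HYP-carrying node unreachable from the reference is also an error, because
silently dropping it would corrupt N.  During aggregation each node's
downstream signs are multiplied by the node's assignment; genes asserted
with contradictory adjusted signs are omitted and reported (the same rule
applied within a single HYP at load time, where a gene curated with both
signs is dropped and counted).

### The four scores

Strength is the sign-adjusted mean of β; GPI projects β onto the unit sign
vector ŝ = s/√N under an fndr-weighted inner product, where fndr_i = 1 −
fdr_i and fdr is the Benjamini–Hochberg adjustment of the raw p-values
over *all* measured genes (array-wide multiplicity, not HYP-local).  The
"fndr" here is the operational 1 − BH-fdr, not an empirical-Bayes local
fdr estimate.  MASS operates on linear-scale abundances; using the average
of treated and control totals in the denominator makes it exactly
antisymmetric.  When a contrast supplies only per-condition log2 values,
linear abundances are derived as 2^x at read time.

EPI treats the signed values x_i = s_i·β_i as evidence for a density on
[−M, M]: for φ > ε the density is proportional to the cumulated magnitude
of the correctly-signed values exceeding φ, symmetrically for φ < −ε, with
a linear bridge across [−ε, ε].  The score is the expectation of that
density.  Two numerical decisions:

- The density uses magnitudes |x_i| on both branches so it is everywhere
  non-negative (a signed negative branch would make the "density"
  negative).
- The 1/(2M) factor that would appear in front of the expectation is
  treated as part of the density normalisation, so the score is a genuine
  expectation over [−M, M] and satisfies |EPI| ≤ M.  A
  `literal_prefactor` flag divides the normalised expectation by 2M
  instead, for users who want the raw convention; it only rescales.

Values with |x_i| > M are clamped to ±M with a logged warning — M is a
saturation bound (default 15, where log2 microarray signal saturates), not
a validity limit.  The implementation integrates the piecewise-constant
density in closed form; the test suite checks it against an independent
oracle that evaluates the density pointwise from its definition and
integrates with Gauss–Legendre panels between discontinuities (agreement
to 1e-6 over 1000 random inputs; observed agreement is ~1e-15).

## Uncertainty

Strength is a weighted sum of normals, so Sd² = (1/N²) Σ sd_i² and the
interval is value ± t(Df, 1−α/2)·Sd with Df from the Welch–Satterthwaite
equation at weights 1/N.  For GPI the fndr weight depends on β_i through
the p-value, so the delta method gives per-gene weights

γ_i = fndr_i + 2·(fdr_i/p_i)·|β_i/sd_i|·t_pdf(β_i/sd_i; df_i),

holding the BH adjustment factor fdr_i/p_i fixed (its own derivative
matters only at large p, where the weight is near zero anyway).  The
absolute value on β_i/sd_i makes γ the true derivative of fndr(β)·β for
either sign of β; the tests verify γ against a central finite difference
to 1e-4.  Sd_GPI² = (1/N) Σ γ_i²·sd_i², and Welch–Satterthwaite uses
weights γ_i/√N, mirroring the variance decomposition.  Zero-variance
inputs collapse the interval to the point score with infinite Df.

MASS and EPI are non-linear, so their intervals come from a parametric
bootstrap: each β_i* ~ Normal(β_i, sd_i²) independently (B = 2000 by
default, minimum 100).  GPI's fndr weights are held at their observed
values during resampling; recomputing the array-wide BH adjustment is not
possible from the aligned inputs alone and the resampling model covers β
only.  For MASS, the resampled fold change is split symmetrically around
the observed per-gene geometric mean abundance (treated* = g·2^(β*/2),
control* = g·2^(−β*/2)), which keeps abundances non-negative by
construction.  The interval is the bias-corrected percentile interval:
z0 = Φ⁻¹(fraction of bootstrap scores below the observed value), endpoints
at bootstrap quantiles Φ(2z0 ± z_{1−α/2}).  When every bootstrap score
falls on one side, the fraction is clamped to 1/(2B) from the boundary to
keep z0 finite.  Note that under strong resampling bias (EPI especially:
adding a second dose of noise systematically inflates it) the
bias-corrected interval can legitimately exclude the point score — that is
the correction working, not a defect.  Cross-checks: the bootstrap
interval for Strength agrees with the analytic one within a few percent
relative width at B = 4000, and 95% intervals cover a known simulated
amplitude in ~95% of replicates when β is drawn from the assumed normal
model.

## Specificity

The null hypothesis is that the score reflects a data-set-wide trend any
comparable gene set would show.  Comparable HYPs preserve the original
signs and sizes but replace each gene with a *different* measured gene of
similar modulation-proneness: all measured genes are ranked by their count
of distinct upstream controllers and cut into cadres of 100 (ties broken
lexicographically; the remainder is merged into the final,
fewest-controllers cadre, which therefore holds 100–199 genes).
Replacements are drawn without replacement within one comparable HYP and
never reuse the original gene at a position; a drawn self-match is
repaired by a swap (or a cyclic rotation among several), which preserves
uniform sampling adequately and guarantees termination.  The p-value
doubles the lesser of the two strict tail fractions over n_null = 1000
comparable HYPs, capped at 1; ties count toward neither tail, and a score
outside the null range reports p = 0 (logged as < 1/n_null).  A naive
mode sampling replacements from the whole universe is provided for
comparison only — it ignores modulation-proneness and is anti-conservative
on real arrays.

## The synthetic generator

`SyntheticSpec` defaults encode the simulated study conditions: a
2000-gene universe, a 100-gene HYP with 25% negative signs, true amplitude
1.0, per-gene standard error 0.5, and t-distributed errors with df = 10 so
the simulated p-values are exactly calibrated against the reported df
(normal errors would make the t-based p-values conservative).  Controller
counts follow a geometric law with mean 5 — a few promiscuously regulated
genes, a long tail of rarely regulated ones — giving cadres realistic
skew.  Abundances split a per-gene log-normal baseline (mean log2 = 7,
SD 1.5) symmetrically so that log2(treated/control) = β exactly, keeping
MASS meaningful.  Consistent random networks are built as a random signed
spanning tree plus extra edges whose signs are forced to close
even-signed cycles; a corruptor flips one cycle edge to produce
guaranteed-inconsistent cases.

What the generator does *not* emulate: probe-level microarray artifacts,
normalisation effects, correlated genes (co-regulation inflates real
score variance relative to the independence assumption), and realistic
signal structure of any particular experiment.  Passing tests therefore
demonstrate statistical correctness of the algorithms under their stated
assumptions, not performance on any real data set.  The stand-in HYP
files written by `write_standin_hyp_suite` are synthetic surrogates shaped
like large literature-curated signatures (unique-gene counts 155, 992,
1741, 80; 4–7% ambiguous genes; a 32-gene overlap between the two largest
related signatures) for exercising the parser at scale; their gene
identifiers are not biology.

## Problem sizes and determinism

The verification suite and `scripts/acceptance.py` use: 1000 random
inputs for the EPI oracle; B = 4000 for the bootstrap/analytic width
comparison and B = 1000 × 1000 replicates for coverage; 1000 simulation
replicates per amplitude for recovery; 200 runs × 1000 comparable HYPs
for specificity calibration and power; and 1000 resamples × 9 contrasts
for the robustness experiment.  These sizes keep Monte Carlo error well
inside the asserted tolerances while completing in minutes on one CPU.
All randomness flows through numpy Generators seeded from explicit seeds
(the CLI and acceptance script derive per-task sub-seeds from a single
root seed), so every run is reproducible bit-for-bit.

## Known limitations

- Per-gene independence is assumed throughout; correlated downstream
  genes make analytic and bootstrap intervals anti-conservative.
- Probe-set collapsing selects per-gene probes but cannot re-fit the
  upstream linear model on the reduced probe set; that refit is the
  responsibility of the differential-expression pipeline.
- HYP genes missing from a contrast are dropped with N reduced (and
  counted) rather than imputed; scores from heavily truncated HYPs should
  be interpreted with the reported n_missing in mind.
- Feedback-loop resolution in inconsistent networks is intentionally
  manual.
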