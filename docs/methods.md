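# Methods

## Dependence model

The analysis rests on one assumption: genes whose transcription depends
on the same regulator are similarly affected when that regulator's
activity or abundance changes. Comparing stimulus-induced fold changes
between a regulator-proficient background (1) and a
regulator-deficient background (2), each induced gene contributes a
point

    x_g = log2 FC_1(g),      y_g = log2 FC_1(g) − log2 FC_2(g).

Both axes are log2 fold changes: induction thresholds are conventionally
stated on the log2 scale, and only on the log scale is the difference
y symmetric between up- and down-modulation. Under pure technical
noise, y is independent of x, E[y] relative to the x-ordering is flat,
and the OLS slope of either half-plane tends to 0 as n grows. Under
complete dependence FC_2 ≡ 0, so y = x exactly and the above-side fit
has slope 1, intercept 0, r² = 1. Real data sit between the limits;
partial dependence (FC_2 = δ·FC_1, 0 < δ < 1) gives y = (1−δ)x, still a
line through the origin with positive slope.

### Per-side regression and bias test

Points with y > 0 (impaired in background 2) and y < 0 (enhanced) are
fitted separately; points with y = 0 exactly carry no asymmetry
information and join neither side. The fit is ordinary least squares
*with* intercept: nothing in the model guarantees the technical offset
between backgrounds is zero, and the intercept absorbs it; the two
limiting behaviors above hold either way. r² is 1 − SS_res/SS_tot
(defined as 0 for constant y), and Spearman's ρ (average ranks on
ties) is reported alongside, as is customary for these dependence
plots. The fit is computed from the closed-form normal equations rather
than through a generic solver so that exactly collinear input yields
r² = 1.0 and slope 1.0 *bit-exactly*, which the test suite asserts.

A side shows systematic dependence when its slope is significantly
nonzero. The default `bias_test="slope_t"` is the two-sided t-test of
the slope (t = b/SE(b), df = n−2). An extra-sum-of-squares F-test of
the fitted line against the fixed line y = 0 (`bias_test="f_vs_zero"`,
F = ((SS₀−SS₁)/2)/(SS₁/(n−2)) with SS₀ = Σy²) is also provided; note
that because each side is *selected* by the sign of y, truncated noise
has a nonzero mean and the F-test rejects almost surely under the null
— it answers "is this side's cloud different from y = 0 at all", not
"does y grow with x". The slope test is therefore the default: its
false-positive rate on pure-noise clouds is controlled near the nominal
alpha (measured ≈ 0.08 at α = 0.05 over 200 simulated clouds; the mild
inflation comes from the distance filter trimming large residuals).

### Iterative distance filter

Starting from all points on a side, each iteration (i) fits the
currently included points, (ii) computes every side point's
perpendicular point-to-line distance |y − a − bx|/√(1+b²)
("Euclidean distance to the regression line"), and (iii) includes
exactly the points within k × (1.4826 × median absolute distance of the
included points); k defaults to 2.5 and previously excluded points may
re-enter. The threshold is proportional to a robust scale estimate of
the current distances, so the rule is scale-free: multiplying all
coordinates by a constant changes neither the inclusion set nor r²/ρ.
The loop stops when an inclusion set repeats — a fixed point or a cycle
(on a cycle the lexicographically smallest set by gene id is reported,
for determinism) — or after `max_iterations` (50), whichever is first;
repetition detection guarantees termination. A side with fewer than
`min_points_per_side` (3) points at any iteration yields a
non-converged fit with an empty inclusion set and bias p = 1, and
produces no dependent calls.

A gene is called `dependent_impaired` iff it is in the converged
above-side inclusion set and that side's bias p < `alpha_bias` (0.05);
`dependent_enhanced` symmetrically below; all other genes are
`independent`. The genes entering the plot default to the background-1
`up` genes (the analysis partitions the induced response); `subset="down"`
runs the repression-side analysis.

## Induction statistics

Fold changes are mean-then-log: log2((mean_stim + c)/(mean_unstim + c))
on normalized group means with pseudocount c = 1 — the conventional
stabilizer, chosen so that zero expression in both conditions gives
log2FC = 0. Significance is a two-sided Welch t-test on
log2(normalized + c) per replicate, BH-adjusted across the tested
genes. This is a deliberately transparent, closed-form-checkable
substitute for moderated DE engines (limma/DESeq); it shares their
thresholds (linear FC ≥ 2 / ≤ 0.5, adj-p < 0.05; preset 1.5/0.66 for
dysregulation scoring) but not their numerics, and gene counts from it
are not comparable to moderated-test counts. Degenerate cases are
resolved by convention so the noise-free simulation mode cannot crash:
fewer than two replicates per group → p = 1 with a warning; both
variances zero with equal means → p = 1; with different means → p = 0.
A configurable expression filter (default: mean normalized value ≥ 1 in
at least one group) drops unexpressed genes before testing; its default
is a choice, not data-derived.

## Normalization

CPM, FPKM and TPM are the standard per-column closed forms; TPM columns
sum to 1e6 by construction and this is validated on the container.
The counts path defaults to CPM (gene lengths optional); FPKM input is
converted to TPM before analysis. Size-factor methods (TMM,
median-of-ratios) are intentionally out of scope.

**Known limitation — composition bias.** Per-million scaling makes each
column sum to a constant, so when a large induced program adds mass to
stimulated libraries (e.g. 25% of genes induced ~4-fold inflates the
stimulated totals by ~0.9 log2 units), all fold-change estimates in
that background shift down by the same offset. Consequences: (i) some
truly induced genes fall below the FC ≥ 2 cutoff and never enter the
dependence plot, (ii) the offset differs between backgrounds, which can
push truly independent genes systematically off y = 0 and, with the
F-test or on the minority side, create spurious calls. The dependence
*classifier* is robust to this (the recovery test below), but
whole-experiment recall through the DE stage is not; correcting it
needs size-factor normalization, which is out of scope here.

## Simulator

`simulate_experiment` draws, in fixed RNG order (lengths, baselines,
induced-gene shuffle, effects, library sizes, counts): gene lengths
uniform on [200, 10000] bp; baseline abundances q_g log-normal
(log-mean 4.0, log-sd 1.2, normalized to proportions); the induced set
as the first ⌈frac_induced·n⌉ ids of a seeded shuffle (impaired genes
first, then enhanced); true effects β_g ~ N(2.0, 0.5) truncated to
[1.2, 4.0] so every induced gene clears the two-fold threshold;
library sizes log-normal around 1e7 (log-sd 0.1). Counts are NB with
mean μ = L_s·q_g·2^(β_g·I[stim]·δ_g) and variance μ + φμ², φ = 0.05 by
default; δ_g is `dependence_factor` (default 0) for impaired genes,
`enhanced_factor` (default 2) for enhanced genes, 1 otherwise.
Replicates per group default to 3.

φ = 0 selects the noise-free mode: counts are the rounded means *and*
every library size is pinned to 1e7, removing all stochasticity. With
δ = 0 the two background-2 condition groups then have bit-identical
columns, their fold change is exactly 0.0, and y = x holds bitwise —
which is what makes the perfect-dependence limit exactly r² = 1 rather
than r² ≈ 1.

What the simulator does *not* emulate: batch effects, isoform
structure, gene–gene correlation, count outliers and single-cell
dropout. Passing tests therefore demonstrate correctness of the
*method* under its own model, not performance on arbitrary real
libraries.

## Enrichment

Upper-tail hypergeometric P(X ≥ k) on the universe-intersected query,
set and collection, Bonferroni-adjusted across the sets actually tested
(the stated convention for these signature analyses; BH is used only
for the per-gene DE step). The default universe is the set of genes
passing the expression filter — the universe choice is genuinely open
and configurable via `--universe`. Only enrichment is tested, not
depletion.

## Verification scale and acceptance checks

The suite verifies: the perfect-dependence limit exactly (2000 genes,
500 induced, noise-free); the null limit on 10,000 synthetic points
(above-side |slope| ≤ 0.02); oracle equivalence of the hypergeometric
tail against exact rational enumeration (all universes N ≤ 12), of BH
against the brute-force step-up (random vectors, n ≤ 20), and of the
OLS fit against hand-computed closed forms and `scipy.stats.linregress`;
parameter recovery on the default noisy simulation (2000 genes, 25%
induced, 80% impaired, φ = 0.05, 4 replicates), where sensitivity and
precision of `dependent_impaired` calls over the genes entering the
dependence analysis are ≥ 0.9 (measured 0.99 and 1.00; the denominator
is the analyzed subset because the DE stage's recall is limited by the
composition bias discussed above, not by the dependence method);
TPM mass conservation; and filter termination on 1000 random clouds.
These sizes keep the whole suite under ~10 s.
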