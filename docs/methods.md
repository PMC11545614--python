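# Methods

## The labeling model

`isotrace` models steady-state isotope labeling on an atom-mapped reaction
network. Each metabolite carries a probability distribution over the 2^k
positional labeling patterns of its mapped atoms (all carbons and nitrogens
jointly, as a bitmask). The balance equation states that a free metabolite's
pattern distribution is the mixture, weighted by per-route source fractions,
of the distributions its producing reactions emit; a reaction maps substrate
atoms to product atoms positionally, combining multiple substrates under the
standard assumption that their pools label independently (condensation =
outer product; cleavage = marginalization). Source metabolites are clamped to
the tracer pattern; declared sinks (CO₂, NH₃) are clamped unlabeled when they
re-enter as substrates (e.g. the carboxylating CO₂ of reductive citrate
synthesis), reflecting dilution in the medium bicarbonate pool.

Keeping the full joint C×N pattern distribution for every metabolite (rather
than factoring per element) costs at most 2^8 states on the canonical network
and makes joint isotopomer read-outs (e.g. C₀¹⁵N₁ vs C₃¹⁵N₁ alanine) exact
marginals rather than approximations.

This is a *steady-state, route-fraction* model, not a kinetic one: the
experimental designs it supports read end-point labeling patterns, and their
conclusions rest on pattern identity (which mass shifts are reachable by
which route), not on time constants. Finite labeling time is emulated by the
generator's turnover parameter (below). Flux estimation — fitting source
fractions to measured MIDs — is deliberately out of scope.

### Solver

The fixed point is found by Gauss–Seidel sweeps in sorted metabolite order
(deterministic), with convergence declared when no pattern probability moves
by more than `tol` (default 1e-10, `max_iter` 10,000). After every update the
distribution is renormalized to sum 1: the exact balance preserves total
probability, but through cycles of condensation reactions the sum direction
of the iteration is unstable, and without the projection floating-point
rounding (~1e-16 per sweep) grows into a deflated spurious fixed point. With
the projection the iteration converges cleanly on all tested networks,
including the full TCA cycle with reversible transaminase loops.

`brute_force_isotopomers` is an independently coded reference solver (pure
Python dictionaries over explicit pattern tuples, exact topological solve for
acyclic route configurations, long Jacobi iteration otherwise) used to
cross-check the vectorized path on networks with ≤ 8 mapped atoms per
metabolite; the two agree to 1e-9 across randomized topologies, tracers and
fraction configurations.

### The canonical network

Carbon positions follow biochemical numbering. Decisions worth recording:

- The aldol split maps FBP C1–C3 → DHAP and C4–C6 → GAP, with
  triose-phosphate isomerase inverting DHAP into the GAP pool; the two routes
  into GAP default to the stoichiometric 50/50 split. This is what forces the
  50% M+2 pyruvate outcome from [1,2-¹³C]glucose.
- PDH releases the pyruvate carboxyl (C1); the acetyl unit is modeled as a
  2-carbon metabolite (the CoA moiety carries no tracer atoms).
- On the first oxidative turn both released CO₂ are oxaloacetate-derived
  (citrate C1 at IDH, α-KG C1 at the dehydrogenase), so acetyl carbons
  survive into succinate — the biochemically correct first-turn bookkeeping.
- Reductive carboxylation is the positional inverse of the oxidative IDH map:
  α-KG C1–C5 → citrate C2–C6 with medium CO₂ filling C1, which forces M+5
  citrate from ¹³C₅ α-ketoglutarate versus M+4 via the oxidative route.
- The oxidative PPP releases G6P C1, making glucose C2 ribose C1 (M+1 ribose
  from [1,2-¹³C]glucose); the non-oxidative entry is a lumped
  transketolase-type reaction transferring F6P C1–C2 onto a triose (M+2, or
  M+4 when the triose is also labeled — even shifts only, preserving the
  classic M+1/M+2 branch discrimination).
- Succinate/fumarate molecular symmetry is not scrambled: a positional
  permutation within a molecule never changes a mass-isotopologue
  distribution, and MIDs are the model's only observable.
- Reversible reactions are two directed reactions (`alt_f`/`alt_r`); which
  direction carries material is a source-fraction parameter, not a
  thermodynamic computation.
- The network is single-compartment. Cytosolic/mitochondrial pool separation
  (relevant to transaminase nitrogen bookkeeping in real cells) is noted as a
  limitation; a `compartment` tag is reserved on `Metabolite` but unused.
- Nucleotide labeling tracks the ribose moiety only (R5P incorporation); base
  carbons are out of scope.

## Natural-abundance and impurity correction

The correction matrix is built at nominal (unit) mass resolution: column *j*
is the expected observed MID when exactly *j* tracer atoms are truly labeled,
combining a binomial purity loss over the *j* labeled atoms with
natural-abundance mass shifts from every remaining atom (¹³C 1.07%, ²H
0.0115%, ¹⁵N 0.364%, ¹⁷O/¹⁸O 0.038%/0.205%, ³³S/³⁴S 0.75%/4.25%; +2 isotopes
convolved as such). Ultra-high-resolution element-resolved correction is an
extension point — the abundance table is overridable — but not implemented.
Correction solves the linear system by non-negative least squares
(`scipy.optimize.nnls`) on the normalized observation and renormalizes,
reporting the residual norm. NNLS avoids the negative fractions plain
inversion produces on noisy data, at the price of a small positive bias in
near-zero fractions (the clip-and-renormalize effect); on noiseless data the
round trip is exact to 1e-9 and on Poisson data at the default depth the bias
is ~1e-4 absolute.

Default tracer purity is 0.99 per labeled atom (typical vendor specification;
configurable). Corrected MIDs are *impurity-corrected*, i.e. comparable to a
pure-tracer simulation; accordingly the synthetic generator simulates truth
with an ideal tracer and folds impurity into the forward matrix, so the
analysis inverts exactly the model that generated the data. Dual-labeled
measurements are corrected per element with two 1-D matrices; a joint C×N
correction is a known extension.

## Enrichment metrics

"Carbon enrichment" in the relative-contribution formula is the
carbon-weighted mean atom enrichment (Σᵢ i·M+i / n), not the labeled fraction:
an M+5 isotopomer should count five times an M+1 isotopomer when apportioning
carbon between glucose and glutamine. The labeled-fraction alternative is one
flag away (`relative_contribution(..., use_labeled_fraction=True)` operates on
whatever per-source statistic is passed). Fold changes are computed from
group means of normalized pools on the linear scale before the log₂
transform.

## Statistics

ANOVA runs per metabolite on log₂ pools; "FDR" is Benjamini–Hochberg (the
default of the common metabolomics platforms); Fisher LSD pairwise t-tests
use the pooled within-group mean square and are gated on the omnibus q-value
(protected LSD). Degenerate metabolites (zero variance) are flagged with
p = 1 rather than dropped. Multivariate steps autoscale by default. PLS-DA
uses the deterministic NIPALS fit on a centered class-indicator response; VIP
is computed as √(p · Σₐ SSYₐ (wⱼₐ/‖wₐ‖)² / Σₐ SSYₐ) with two components by
default, so mean(VIP²) = 1 identically. PCA components are sign-fixed
(largest-magnitude loading positive). Clustering uses 1 − Pearson distance
with average linkage; items are pre-sorted by id for deterministic tie-breaks
and zero-variance rows get distance 1 with a warning.

## Synthetic data: what it emulates and what it does not

The generator draws, per group: replicate pool sizes (lognormal around the
group mean, CV 10% default), a per-sample multiplicative lognormal scale
(technical effect, CV 10% default), and Poisson ion counts at a mean depth of
1e6 counts per unit pool size. True MIDs come from the label simulator under
group-specific route fractions, mixed with an unlabeled pre-existing pool by
a turnover fraction (default 0.8) that stands in for finite labeling time.
All randomness flows through one seeded `numpy` Generator; identical seeds
give byte-identical datasets.

Three presets mirror the supported experimental designs with n = 3
throughout (triplicate design):

- `cell_cycle` (G1/S/G2): S-phase elevation (2-fold) of lactate, nucleotides,
  ribose phosphate, alanine, pyruvate and α-ketoglutarate; nucleotides stay
  elevated into G2.
- `lcl_vs_lymphoma`: alanine 4-fold and lactate 2–4-fold above the
  non-malignant line (4-fold and the 2–4 range are the stated effect sizes;
  other contrasts default to 2-fold), with a heavier oxidative-PPP share in
  the lymphoma lines.
- `fludarabine`: four groups (± drug × LCL/lymphoma); untreated lymphoma runs
  lower glycolytic and glutamate pools but higher TCA/nucleotide/lactate/
  alanine pools; the drug reverses both features in lymphoma only (2-fold
  glycolytic accumulation, 2–4-fold product collapse), moving treated
  lymphoma toward the LCL profile in PCA space.

What the generator does **not** emulate: chromatographic artifacts, missing
peaks, heteroscedastic detector noise, secreted-metabolite exchange with the
medium, isotopic non-stationarity, or compartment-specific pools. Passing
recovery tests on this generator therefore demonstrates correctness of the
inference chain under its stated noise model, not robustness to every failure
mode of real LC-MS data.

## Regulatory-network filter

Metabolic genes must clear a median log₂ expression floor (default 10) in
both cohorts (patients and cell lines) and regulators their own floor
(default 7.5); edges to removed nodes are dropped; regulators must then keep
a minimum degree (default 5). Because removing a regulator can orphan genes
and vice versa, the degree filter and edge pruning are iterated to a fixed
point, which makes the result independent of the order in which the filters
are stated; the filter is idempotent on its own output. Counts at each stage
are reported for auditability. The loader accepts any association table in
the declared TSV schema, so a real enhancer/promoter snapshot can be
substituted for the synthetic fixtures used in tests.

## Numerical choices and degenerate inputs

- Simulator: tol 1e-10, max 10,000 sweeps, sorted-id iteration order,
  per-sweep simplex projection; unreachable metabolites are reported
  (all-M+0, flagged) rather than raised.
- Correction: NNLS; all-zero ion counts raise an undefined-MID error;
  corrected vectors are renormalized and never negative.
- Statistics: all-identical values flag degenerate with p = 1; constant
  matrices/references raise; BH q-values are monotone in p-rank by
  construction.
- Sizes used by the validation suites: oracle comparisons run 100 randomized
  networks of ≤ 4 metabolite tiers and ≤ 3 carbons each; recovery uses the
  three presets at n = 3 over 200 generations; calibration uses 1,000
  twenty-metabolite null/power tables and 200 VIP tables of 50 features.

## Known limitations

- Single compartment; no exchange-flux or kinetic modeling; no inverse
  (flux-fitting) problem.
- Nominal-mass correction only; per-element correction of jointly labeled
  C/N metabolites.
- NNLS positive bias at truth-zero fractions (order 1e-4 at default depth) —
  visible only against the very small sampling errors of high-depth data.
- The canonical network is a teaching-scale central-carbon map, not a
  genome-scale reconstruction; users can extend it via YAML or the builder's
  `extra_metabolites`/`extra_reactions` hooks, with atom conservation
  validated on load.
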