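# Methods

## The landscape and its parameterisation

The object of study is a complete 8 × 16 factorial of TF:RE complexes:
three two-state recognition-helix sites (25 glu/GLY, 26 gly/SER,
29 ala/VAL; lower case ancestral, upper case derived) crossed with two
four-state RE half-site positions (3 and 4, forward strand). The
response variable is ΔG_dissociation = −RT ln K_d in kcal/mol with
K_d in molar, R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹ and T = 298.15 K by
default (both configurable and recorded in outputs). Larger ΔG means
tighter binding, so positive effects raise affinity.

Because ΔG is a free energy, additivity of genetic effects on the ΔG
scale is the natural null model, and epistasis is defined as any
deviation from it.

## Encodings and the model hierarchy

Protein sites enter the regression as single ±1 coordinates (ancestral
−1, derived +1); nucleotides enter via the tetrahedral WYK embedding,
A = (1,−1,−1), C = (−1,1,−1), G = (−1,−1,1), T = (1,1,1). Every
interaction column is the elementwise product of its factor columns.
These choices make all columns mean-centred contrasts, so on the
complete balanced factorial the design is exactly orthogonal: the
intercept is the grand mean, each group's coefficients are unchanged by
the presence of other groups, and sequential R² increments are
order-invariant. The term groups, in their canonical nesting order, are
INTERCEPT, P1, P2, R1_3, R1_4, R2, X2, X3 (85 columns in all), with a
three-way intra-protein group P3 (abc) available but off by default —
the cross-interface third-order terms (protein × RE-pair and
protein-pair × nucleotide) are the scientifically motivated third-order
family here, and the hierarchy mirrors that emphasis.

Effects are reported on the state scale rather than the coefficient
scale: a nucleotide's main effect is the dot product of its site's
(w, y, k) coefficients with its WYK vector (deviations from the grand
mean, summing to zero over the four states); a pair contrast is the dot
product of the nine R2 coefficients with the outer product of the two
state vectors (zero row/column sums); a protein substitution's total
effect is twice its coefficient; a protein-pair interaction is reported
in the "marginal" convention (2 × coefficient — the substitution's
effect in the partner's derived background minus its average effect),
with the classical double-mutant-cycle magnitude (4 × coefficient)
available behind a flag. Cross-interface effects are twice the relevant
cross-coefficient contrast and equal the difference in a nucleotide
effect (or pair contrast) between derived- and ancestral-background
subset fits; this identity is exercised as a test oracle.

A redundant 0/1 indicator encoding ("binary") is carried as a
cross-check. Its one-hot blocks are collinear with the intercept, so
those fits use minimum-norm least squares and effects are extracted
from fitted cell means through the definitional contrasts. The
projection spans the same column space as the WYK design, and equality
of all extracted effects between encodings is property-tested on random
landscapes. Rank deficiency in the WYK design, by contrast, indicates a
genuinely unidentifiable model for the supplied observations and raises
an error naming the collinear terms.

## Fitting, likelihoods and model comparison

Coefficients are ordinary least squares (statsmodels under the WYK
encoding). Log-likelihoods are Gaussian with the error variance
profiled at its MLE; the residual sum of squares is floored at 1e-300
so that interpolating (zero-residual) fits remain finite — such fits
are never used for inference. Nested models are compared with the
likelihood-ratio statistic 2·Δllf against an asymptotic χ² with df =
number of added columns, plus the adjusted-R² increment (which may be
negative and is reported signed). Bonferroni correction uses the number
of comparisons in the current run by default, configurable and recorded
in the output JSON. The χ² reference is asymptotic: at the full
replicate-level table (384 rows) the simulated null rejection rate at
α = 0.05 is ≈ 0.04–0.07, which the acceptance suite checks; on much
smaller tables (e.g. 48 rows per protein with 9 added parameters) the
test is visibly anticonservative, which is inherent to the asymptotics
rather than to the implementation.

Fitting uses replicate-level observations, not cell means: the
per-protein RE model {INTERCEPT, R1_3, R1_4, R2} is saturated at the
mean level (16 parameters for 16 cells), so LRTs and adjusted R² are
only informative with replication. Energy logos are built per protein
from that model: three columns (site-3 main, site-4 main, pairwise
epistasis) with state heights ranked by magnitude, column widths equal
to the sequential adjusted-R² increment (floored at zero for display;
numeric tables keep signed values), and significance stars from
per-column LRTs — each site tested by adding its first-order terms to
the other-site-only model, the epistasis column by adding R2 to the
two-site first-order model.

## Binding curves

Titrations are fit to the single-site anisotropy model
A([P]) = A_free + (A_bound − A_free)·[P]/(K_d + [P]) by bounded
nonlinear least squares, optimising log₁₀K_d so all parameters are
O(1). Initialisation: baseline = minimum anisotropy, plateau = maximum,
K_d = concentration nearest half-maximum, with up to five log-spaced
restarts; non-convergence is a flagged result, not an exception. A
probe-depletion-corrected quadratic variant is available behind a flag
for K_d values near the 5 nM probe concentration; the hyperbolic model
is the default since most fitted K_d in this system lie far above the
probe concentration. A range flag marks K_d estimates outside the
titrated concentration interval. Replicates are summarised by mean and
SEM (sample sd/√n; undefined and flagged for n = 1).

## Functional criteria and pathway analysis

A complex is functional when (1) its mean ΔG is strictly greater than
the grand mean over all 128 complexes and (2) it lies within a fold
factor (default 10) of its protein's best target, implemented in energy
space as ΔG ≥ bestΔG − RT·ln(fold) (1.364 kcal/mol at default
constants); ties for best target are all retained, and both thresholds
are recomputed from the supplied landscape. Scenario 1 evaluates the
3! orderings of the RH replacements, requiring every intermediate
protein — endpoints included — to keep at least one functional RE.
Scenario 2 runs exact breadth-first connectivity on the neutral network
(functional complexes joined by single moves), with shortest-path
enumeration capped (default 10,000) on permissive landscapes.
Gating classifies, for each functional node g and admissible move m,
every other move m′ applicable both before and after m: permissive if
m′ becomes admissible only after m, restrictive in the converse case;
cross-molecule events are flagged separately from same-molecule ones,
and moves are defined as "set position p to state s" so the same move
is comparable across contexts.

Note one structural fact: the strict-inequality mean criterion can
never call all 128 complexes functional, so the fully connected
576-edge network is exercised from an explicitly supplied functional
set rather than from a classifiable landscape.

## Structural-feature regressions

Per-complex summary features (hydrogen-bond counts, contact-pair
counts) are regressed on ΔG by simple OLS, globally or within each
protein's 16 REs; classification is positive/negative at p < α
(default 0.05, unadjusted, matching the per-panel presentation such
data are usually given; a Bonferroni option exists) and NS otherwise,
with zero-variance features flagged NS. Fits are unweighted on feature
means; replicate SEMs are carried for display only.

## The synthetic-data generator

The generator is the exact inverse of the regression contracts.
Parameters are specified in effect space — zero-sum state effects per
RE site, doubly-centred 4 × 4 pair-contrast matrices, protein effects
and pair marginals on the 2×-coefficient scale, cross-interface shifts
as the derived-minus-ancestral change in a nucleotide effect or pair
contrast — and converted internally to per-cell contributions, so a
noiseless generated landscape returns every injected parameter exactly
through the fitting pipeline (property-tested over 500 random valid
parameter sets). Replicates add independent Gaussian noise
(`numpy.random.default_rng(seed)`, byte-reproducible per seed).

Defaults emulate the study design: 8 × 16 cells, 3 replicates, and
Gaussian replicate noise of sd 0.2 kcal/mol — a typical technical
spread for triplicate anisotropy-derived free energies. The AncSR1
preset carries the four text-reported magnitudes (G3 +1.0, T4 +0.5,
G3×T4 +0.8, glu25GLY +1.3 kcal/mol) tagged `provenance="paper"`;
every other determinant is shown in the source only graphically and is
therefore a placeholder of realistic sign and magnitude, tagged
`provenance="placeholder"` so invented numbers cannot masquerade as
measured ones. Zero-sum balancing of a specified state effect is spread
evenly over the unspecified states (the minimal-assumption completion).
What passing tests on these landscapes show is that the estimators
recover the generating process they assume — Gaussian, homoscedastic,
replicate-independent noise on a complete factorial; they do not show
robustness to censored high-K_d measurements, heteroscedastic errors,
batch structure, or missing cells, none of which the generator
emulates.

## Problem sizes and numerical choices

Simulation-based checks use: 100 seeded landscapes for encoding
equivalence and for graph/path oracle equivalence, 500 for the
generator round trip and for CI calibration, 1000 for the LRT null
rate, 100–200 for Monte-Carlo K_d recovery and feature-classification
rates — sizes chosen to make binomial sampling error small relative to
the asserted tolerance bands. Exact identities are asserted at 1e-9
(regression algebra) or 1e-12 (scalar conversions). Tie-breaking is
deterministic everywhere (canonical genotype order: ancestral first,
then Hamming distance, site 25 varying slowest; REs lexicographic), and
all tabular outputs serialise floats with 17 significant digits so
runs are reproducible byte-for-byte from config plus seed.

## Known limitations

- Only the 3-site/2-state × 2-site/4-state space is supported; the
  encoding machinery would generalise but is neither exposed nor tested
  beyond it.
- The functional criteria are a deliberately simple step function from
  affinity to function; no population-genetic weighting (fixation
  probabilities, mutation biases) is applied to paths.
- Per-protein logos inherit the small-sample caveats of the χ² LRT
  noted above; stars on 48-row fits should be read conservatively.
- Cooperative dimer binding on palindromic full sites is out of scope;
  all energies refer to half-site association.
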