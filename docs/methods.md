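# Methods

## Model

`divloc` implements the degree-of-uniformity signed measure and its recursive
Hahn decomposition for finite discrete distributions and univariate
piecewise-monotone densities.

For a part *P* (any subset of atoms; any finite union of open intervals):

- mass c_P = Σ_{i∈P} p_i or ∫_P p(x) dx;
- conditional entropy H_P = −Σ (p_i/c_P) ln(p_i/c_P) (or the integral
  analogue), in nats, with 0·ln 0 := 0; continuous H_P is a differential
  entropy and may be negative;
- diversity D_P = e^{H_P} (Hill number of order 1; equals K for a discrete
  uniform over K atoms and the support length for a continuous uniform);
- degree of uniformity dou(P) = D_P/c_P, always positive;
- signed measure against a reference value r: m_r(P) = c_P ln(dou(P)/r).

The split of a part A uses the threshold t = c_A/D_A = 1/dou(A) and the
pointwise characterization of strict sets: P_A = {p < t}, Z_A = {p = t},
N_A = {p > t} are the maximal strictly-positive / null / strictly-negative
subsets of A under m_{dou(A)}.  The recursion splits P- and N-children,
leaves Z-children terminal, and carries them into deeper level views, which
preserves the strict left-to-right ordering of dou within every level.

Assumptions: discrete supports are finite (an infinite pmf must be truncated
by the caller); continuous densities are integrable with finite entropy,
declared piecewise monotone/constant with finitely many segments, and parts
are finite interval unions (the splitter only ever produces these for such
densities).

## Level indexing

The root is level 0; level k holds the parts produced by k split rounds plus
all terminals created earlier.  In the field's example write-ups the same
four-part binomial partition is often labeled "Level 2", matching this
package's `level_view(tree, 2)`.  Note that some further refinements are
commonly quoted one level earlier than the strict recursion produces them;
`divloc` always reports the level at which the faithful recursion creates a
part (e.g. for Binomial(8, 0.4) the parts {7,8} and {0} arise at level 4 as
children of the level-3 part {0,7,8}).

## Parameters and numerical choices

- **Mass validation** `tol = 1e-9` on |Σp − 1| (configurable); a
  `renormalize` flag accepts count/percentage histograms.  Zero-probability
  atoms are dropped at construction and flagged, so 0·ln 0 never arises.
- **Null-band tolerance** `z_rtol = 1e-9` (relative to the threshold):
  exact equality p_i = c_A/D_A almost never survives floating point, so
  atoms within the band are assigned to Z; ties between band and strict side
  resolve toward Z, keeping designed null sets intact under rounding noise.
  The brute-force maximality oracle uses an absolute measure tolerance
  `m_tol = 1e-9` on m(S); atoms engineered to sit pathologically close to a
  threshold without equalling it could in principle be classified
  differently by the two routes.
- **Level-set roots**: each declared monotone segment is scanned on a
  1024-point grid for sign changes of p(x) − t, then refined by Brent's
  method to |Δx| ≤ 1e-10; the exponential family uses the closed form
  x = −ln(t/λ)/λ.  A declared-monotone segment whose sampled values
  contradict the declaration is rejected at construction.
- **Constant segments** count as "at level" when |h − t| ≤ 1e-9·max(t, 1);
  isolated crossing points have measure zero and are never placed in Z.
  Interval endpoints are treated as open throughout; boundary points carry
  no mass.
- **Infinite tails** use closed forms where the family provides them
  (exponential mass, mean, and entropy on any interval); generic densities
  fall back to adaptive quadrature, and tails are truncated for sampling
  and bracketing where the remaining mass drops below 1e-12.
- **Stopping rules**: discrete trees terminate naturally at singletons and
  uniform parts (a part whose split returns only Z); continuous trees default
  to `max_depth = 3` since the refinement of a continuous density has no
  natural end.  An optional `min_mass` guard (off by default) prunes
  branches below a mass floor.
- **Display** rounds dou to 2 decimals by default (CLI `--round`); stored
  values are full precision, and the JSON export round-trips bit-identically.

## Null-set designs

A design fixes whole-distribution diversity D, null mass c_Z, and factors
η₁ > 1, η₂ ∈ (0,1) so that dou(P) = Dη₁ and dou(N) = Dη₂.  Geometric-mean
conservation forces η₁^{c_P} η₂^{c_N} = 1 with c_P + c_N = 1 − c_Z, whose
unique solution is

    c_P = −ln η₂ (1 − c_Z)/(ln η₁ − ln η₂),
    c_N =  ln η₁ (1 − c_Z)/(ln η₁ − ln η₂).

The numerators must be cross-assigned this way: the same expressions with
ln η₁ and −ln η₂ swapped satisfy the constraint only in the symmetric case
η₁η₂ = 1 (e.g. η₁ = 2, η₂ = 1/2, where both assignments coincide).  One
formulation in circulation prints the swapped form; `divloc` implements the
constraint-consistent one and asserts η₁^{c_P} η₂^{c_N} = 1 on every solve.
Discrete realizations additionally need the atom counts n_P = c_P D η₁,
n_Z = c_Z D, n_N = c_N D η₂ to be integers; infeasible designs are rejected
with the offending counts named.  Only single-band, piecewise-constant null
designs are supported.

## Synthetic fixtures

Two applied example classes are emulated by seeded generators (no real
datasets exist for them; they are synthetic stand-ins):

- `fixture_incidence` — a strictly unimodal histogram over 20 five-year age
  bands, multiplicative decay ≈ 0.8 per band away from the peak with ±15%
  jitter, peak mass ≈ 12%.  Strict unimodality with no ties means every
  split is binary (Z empty), the behaviour expected of generic empirical
  histograms.
- `fixture_monotone_load` — strictly increasing shares over 21 positions
  (cumulative sums of jittered positive increments), ≈ 10% at the loaded
  end.

Both are pure functions of (parameters, seed).  They reproduce the
qualitative structure that matters for the decomposition — strict
monotonicity/unimodality, no ties, realistic peak masses — but not
sampling noise, age-structure artefacts, or measurement error of real
surveillance or sensor data; passing tests on them demonstrates the
machinery, not epidemiological validity.

## Problem sizes and verification

All shipped checks run on desk-scale inputs: 9–12-atom discrete
distributions, the rate-2 exponential to three levels, 100-fold random
partition/pair property checks, 200-pair monotonicity audits, and
brute-force subset enumeration up to 2¹² subsets.  The whole suite runs in
a few seconds.  Closed-form continuous summaries are cross-checked against
adaptive quadrature; the binomial pmf recurrence is cross-checked against
an independent statistics library; maximality of the split members is
confirmed by exhaustive enumeration.

## Known limitations

- No multivariate densities; no densities with infinitely many monotone
  segments; no symbolic entropy beyond the built-in closed forms.
- Discrete supports must be finite; infinite discrete distributions need
  caller-side truncation, for which no canonical rule is provided.
- Hill numbers of order q ≠ 1 (Rényi-based diversities) are out of scope.
- The continuous recursion has no natural termination; depth is a choice.
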