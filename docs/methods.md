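# Methods

## Model

A cell carries a plasmid at fixed copy number *n*; *i* of the copies bear the
mutant allele. Cells divide at rate λ_i = 1 + s(n, i) and die at rate μ = 1,
independently (branching approximation: no resource competition, justified
while the focal lineage is rare and the resident population is declining).
Fixing μ = 1 sets the unit of time to the mean cell lifespan; results for any
other death rate follow by rescaling time (`rescale_time`).

Fitness functions (both require declining homozygotes, s(n,0) < 0 and
s(n,n) < 0, and s > −1 so that birth rates stay nonnegative):

- **dominant**: s_min for i ∈ {0, n}, s_max otherwise — one copy of either
  allele confers its full effect;
- **peaked**: s_max − (2(s_max−s_min)/n)·|i − n/2| — maximal at the balanced
  mixture, linear in the imbalance. For odd *n* the half-integer |i − n/2| is
  used exactly; no rounding.
- **custom** tables are accepted under the same two constraints. Gene-dosage
  dependence of s_max on *n* is not modelled (custom tables can emulate it
  per-*n*).

Division kernels. Under *regular* replication every copy is duplicated
(2i mutant copies of 2n) and daughters receive hypergeometric splits; under
*random* replication the pool grows by duplicating uniformly chosen copies
(Pólya urn) to 2n before the same split. Kernels are computed in exact
rational arithmetic for n ≤ 30 (printed fractions such as 2/3 and 5/9 are
reproduced bit-exactly) and in floating point above; they are cached per
(n, mode). Binomial convention: C(−1, 0) = 1, all other out-of-range
binomials are 0 — this is what makes the urn pmf collapse to point masses at
i = 0 and i = n. Unordered daughter pairs are stored keyed (min, max) with
the factor 2 for distinguishable daughters folded into the stored
probability.

## Extinction fixed point

Extinction probabilities Q_0..Q_n solve z = f(z) with
f_i(z) = (1−ρ_i) + ρ_i Σ_{{j,k}} P(i→{j,k}) z_j z_k, ρ_i = λ_i/(λ_i+1); the
relevant solution is the least fixed point, the limit of the componentwise
nondecreasing iterates from z = 0.

Numerics. Plain iteration contracts at a rate that approaches 1 near the
critical threshold, and its residual then underestimates the remaining error
by 1/(1−rate). The solver therefore interleaves blocks of plain sweeps with
safeguarded Newton steps on z − f(z) = 0 (analytic Jacobian; for monotone
polynomial systems Newton from the sub-solution region converges to the
least fixed point), and finishes with a Newton polish driven by the *step
size* — a direct estimate of the distance to the root — rather than the
residual. Safeguards: a step overshooting above 1 by more than the snap
tolerance is rejected (the all-ones vector is always a root of the system;
accepting a step clipped onto it would pass any residual test), as is a
polish step larger than the remaining-error bound. Tolerance: sup-norm
residual 1e−12, sweep cap 1e6.

Snapping. Components of Q within 1e−7 of 1 are reported as exactly 1 and
establishment probabilities below 1e−7 as exactly 0, making "establishment
is impossible" an exact statement at and below threshold. The snap cannot be
much tighter: at critical parameters the fixed point is a double root at 1,
which double precision localizes only to ~√ε ≈ 1e−8. The snap is still two
orders below the ~1e−5 establishment probabilities produced at the 1e−4
bisection resolution used to verify the thresholds, so threshold location is
unaffected.

Establishment. Regular mode: P_est = 1 − Q_1 (the mutation appears on one
copy in one cell). Random mode: the new mutant copy can be amplified by the
urn within the same cell cycle, so the lineage may start from m = j+k copies
split {j, k} over two daughters; P_est averages 1 − Q_j Q_k over the
conditional head-start distribution
pmf(m) = (2n+(n−1)m)/(n·m·(m+1)) · C(n,m)/C(2n−1,m) composed with the
hypergeometric split. n = 1 has no heterozygote class; establishment is
defined as 0.

The Monte-Carlo cross-check simulates the embedded discrete-time process for
whole cohorts of lineages simultaneously (vectorized binomial/multinomial
draws per type and generation). A lineage counts as established when its
living mutant-carrying cells reach 500 — from there, extinction probabilities
are astronomically small for every parameter set tested (< 1e−6 even at the
most nearly-critical grid point) — and replicates exceeding the event cap
(default 1e7 processed cells) are flagged and excluded rather than counted.
Wild-type daughters are dropped from lineages: they carry no mutant copy and
die out with probability 1.

## Rescue

The declining wild-type population is treated deterministically,
N(t) = N₀ e^{s(n,0)t}; each of its divisions yields a successfully
establishing mutation with probability u·n·P_est (at most one mutation per
division), so successful mutations form an inhomogeneous Poisson process
with intensity u·n·P_est·λ₀·N(t). Closed forms follow for P_rescue, the
conditional CDF of the first-success time, its median (bracketed bisection)
and mean (adaptive quadrature of the survival function; cross-checked in the
tests against inverse-CDF sampling). All analytic quantities depend on u and
N₀ only through the product uN₀, which is therefore the canonical input; the
simulator needs them separately and defaults to the split u = uN₀/1000,
N₀ = 1000 — a large declining population with rare mutations, the regime the
Poisson approximation assumes.

## Spectral analysis

The expected-progeny matrix M (entry i,j: expected daughters with j mutant
copies per type-i parent) factors as 2RP in regular mode with R = diag(ρ_i)
and P the segregation marginal. The eigenvalues of P are
χ_i = 2ⁱ C(n,i)/C(2n,i) (χ₀ = χ₁ = 1, nonincreasing). Establishment is
possible iff the leading eigenvalue of M exceeds 1, giving the closed-form
thresholds on s_max and (inverted, open-boundary, so equality means no
establishment) on n. The stationary cell type distribution of an established
population is the normalized leading left eigenvector of M (dense solver;
homozygote classes included — segregation constantly replenishes them); it
exists only for supercritical models, and a subcritical request raises an
error rather than returning a vector. Under random replication with dominant
fitness the interior block of M/(2ρ_het) has the all-ones left eigenvector
with eigenvalue (n−1)(2n+1)/((n+1)(2n−1)) — heterozygote types are equally
abundant in the long run. The long-run growth rate of a rescued population
is (1+s_max)(2χ−1)−1 with χ the largest segregation eigenvalue below 1; this
and the threshold identities are verified numerically (eigensolver, and
bisection on the branching solver to 1e−4) rather than symbolically. The
comparison threshold 1/(2^{n−2}−1) of the simplified all-balanced-
heterozygote model is provided for n ≥ 3.

## Cointegration

Cell types are multisets of molecules, each molecule a multiset over the two
alleles; an m-mer counts m-fold against the copy number. Canonical form
sorts molecules by (size, composition); the state space is enumerated
exhaustively (capped at n = 8 by default — 591 states; the cap is a guard
against combinatorial growth and can be overridden). Fitness is dominant and
depends on allele counts only.

Division duplicates every molecule and distributes the 2M labeled copies
uniformly over all assortments giving each daughter exactly n copy-number
units. The paper-facing consistency check for this choice of segregation
measure: all-monomer cells reproduce the regular-replication kernel exactly
(asserted as an identity over Fractions), and constrained types such as
(AAA)(B) breed true. Fusion picks a uniformly random unordered molecule pair
and concatenates it; single-molecule cells cannot fuse (κ_a = 0); there is
no resolution of cointegrates. One fusion at most per cell cycle, applied
before division in the extinction recursion (the ordering does not affect
rates, which depend on allele counts alone). The recursion mixes fused and
unfused division kernels with weights κ and 1−κ and is solved by the same
least-fixed-point machinery as the base model. Establishment starts from the
all-monomer type (A)^{n−1}(B); κ = 0 reduces exactly to the base regular
model, and κ = ∞ (immediate fusion of everything into one heterozygous
multimer) gives the single-type closed form s_max/(1+s_max), an upper bound
for every finite κ.

## Gillespie simulation

Exact direct-method simulation (no tau-leaping): per-type aggregated rates,
exponential waiting times, categorical event selection. Mutations occur only
at divisions of fully wild-type cells (probability u·n per division), each
founding a tagged lineage so the first mutation whose descendants are alive
at the horizon — the "first successful rescue mutation" — is identifiable
afterwards; cells that segregate back to fully wild type rejoin the untagged
pool. An optional `recurrent_mutation` flag (off by default, sensitivity
analysis only) lets heterozygous cells mutate their remaining wild-type
copies via a post-segregation approximation.

State is recorded on a fixed time grid. Runs stop at extinction, at the time
horizon, at a population cap (rescued populations grow exponentially and
would otherwise dominate the runtime), or at an event cap (flagged as
truncated). Grid points after the stop time repeat the final snapshot —
exact for extinct runs, frozen for capped ones — so analyses that need live
samples (e.g. growth-rate estimation) must restrict to times ≤ `stop_time`;
`growth_slope` does this and measures the two-point log-slope of the
mutant-carrying population from the first sample with ≥ 300 cells to the
last live sample, requiring at least 4-fold growth in the window.

Study conditions for the simulation-vs-theory closure: n = 4, regular,
dominant, s_max = 1.0, s_min = −0.1, uN₀ = 0.1 split as u = 1e−4, N₀ = 1000;
200 replicates; horizon t_max = 150 mean lifespans — comfortably beyond the
wild-type extinction time ln N₀/|s₀| ≈ 69 plus its fluctuation tail, so
"alive at the horizon" coincides with "rescued" (at shorter horizons the
still-declining wild-type inflates the survival count); population cap 6000.
At these sizes the surviving fraction is compared to the Poisson closure at
3 binomial standard errors and the survivor growth slope to
(1+s_max)(2χ−1)−1 = 3/7 at 3 standard errors of the mean.

## What the generator emulates — and does not

The simulator realizes exactly the process the analytics describe:
density-independent birth-death, fixed copy number, no horizontal transfer,
no standing variation, no recurrent mutation inside mutant lineages, no
cointegrate resolution, fitness constant in time. Agreement between
simulation and formulas therefore validates the derivations and the code,
not the biological adequacy of those assumptions: real populations have
carrying capacities (the branching approximation overestimates late-time
growth), plasmid copy numbers fluctuate around their set point, conjugation
and copy-number evolution exist, and mutation input from the rescued
lineage itself is neglected. Results near the critical thresholds are also
asymptotic statements — establishment probabilities just above threshold are
positive but tiny, and waiting times to establishment diverge.

## Numerical choices at a glance

| Quantity | Choice | Why |
| --- | --- | --- |
| Kernel arithmetic | exact Fractions for n ≤ 30 | bit-exact printed fractions |
| Fixed-point tolerance | 1e−12 sup-norm, cap 1e6 sweeps | far below all snap/test tolerances |
| Snap to boundary | 1e−7 | above the √ε double-root floor, below threshold-scale P_est |
| MC establishment | 500-cell survival criterion, 1e7-cell event cap | residual extinction < 1e−6; flagged not counted |
| Threshold bisection | bracket (0.01, 16), tol 1e−4 | covers all thresholds for n ≥ 2 (max 8 at n = 2 random) |
| Cointegration cap | n ≤ 8 (591 states) | exhaustive enumeration stays instant |
| Gillespie closure | 200 reps, N₀ = 1000, t_max = 150, cap 6000 | survival ≡ rescue; ~1 minute on one core |
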