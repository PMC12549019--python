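# Methods

## The model

A circular genome of length `L_G` (together with its reverse complement) is
stored collectively in a pool of RNA oligomers: every oligomer carries a
subsequence of the genome, and no full-length copy exists.  Two length scales
characterize the genome's motif structure:

* `L_U`, the unique motif length — the smallest `L` such that every length-`L`
  motif occurs at most once across genome and complement.  Oligomers of length
  `>= L_U` address a unique locus ("VCG oligomers"); shorter ones are
  feedstock.
* `L_E`, the exhaustive coverage length — the largest `L` for which all `4^L`
  motifs occur.

Since genome plus complement hold only `2 L_G` motifs,
`L_U >= L_U_min = ceil(log4(2 L_G))` and `L_E <= L_E_max = floor(log4(2 L_G))`.
The bundled 16-nt example genome `AAAGAGGACACGGCAU` attains both bounds
(`L_E = 2`, `L_U = 3`).

Strands hybridize into complexes of up to four strands.  The energy model is
a simplified nearest-neighbor scheme: each block of two Watson–Crick pairs
contributes `gamma` (default −2.5 kT, roughly the average stacked-pair energy
of RNA duplexes), each dangling-end block `gamma/2`, and a nick — two strands
abutting over a paired template — closes one full block.  Mismatched blocks
carry a `gamma_MM = +25 kT` penalty in the stochastic model; the default
policy simply rejects mismatched placements, which is the effective behavior
at that penalty.  Dissociation constants follow
`K_d = c° exp(E/kT)` with `c° = 1 M`; association happens at the encounter
rate `k_enc = 1/(c° t0)`, with the encounter time `t0` (≈ 1 µs for absolute
estimates) as time unit.  Templated ligation joins two nicked strands at
`k_lig = 1e-12 / t0`; under "kinetic suppression" only ligations
incorporating a monomer retain a nonzero rate.

Because pools are sequence-unbiased, complexes are tracked coarse-grained by
strand lengths and alignment indices only.  Each configuration represents
`C(cfg)` explicit sequence realizations: `C(L) = 4^L` below `L_U_min`
(every sequence occurs), `2 L_G` above (each motif occurs once), and partner
strands contribute `C(L)/4^overlap` admissible sequences while the overlap is
shorter than `L_U_min`, exactly one once the overlap pins a locus.  Five
geometry classes exist up to four strands (duplex, ternary, 3-1, and left-
and right-tilted 2-2 complexes); 2-2 complexes are deduplicated against their
180°-rotated representation (lexicographically smaller representative kept,
multiplicity halved when rotation-symmetric; equal-length duplexes likewise
carry a factor ½ for unordered strand pairs).

## Adiabatic equilibrium

Ligation (1e-12/t0) is far slower than any (de)hybridization timescale, so
binding pre-equilibrates at fixed strand lengths.  For every pooled length
one mass-conservation equation couples the free per-sequence concentration to
all complexes containing that length; complex concentrations follow mass
action with effective association constants `Ka = C(cfg)/K_d(cfg)`.  The
resulting fourth-degree polynomial system is solved by Levenberg–Marquardt in
log per-sequence concentrations (positivity for free; the pM–mM dynamic range
is then well conditioned), initialized at free = total, with a damped
continuation in total concentration as fallback.  Relative conservation
residuals are required below 1e-10.  All bookkeeping is aggregated by length
multiset — the solver and every observable need only sums of `Ka` per
(lengths, channel-class) group — so the per-iteration cost is set by the
number of length combinations (hundreds), not configurations (up to ~3e5 for
the 9-length pool).

## Observables

All replication observables are ratios of nucleotide-incorporation fluxes
through ligation-competent (nicked) complexes, each junction weighted by the
shorter educt length.  Yield is the flux fraction whose product reaches
`L_U`; fidelity weights the VCG-producing flux by the correct-product
probability

    p_corr = C(Le1+Le2) C(Lo1) C(Lo2) / [C(Lo1+Lo2) C(Le1) C(Le2)],

the ratio of genome-compatible products to all products realizable from a
nick with educt lengths `Le` and educt–template overlaps `Lo` (capped at 1
defensively for biased genomes); efficiency is their product.  Ligation
shares split the flux by educt classes (F+F, F+V, V+V, with correct/false
and 1+1 sub-labels).  The monomer-extension-competent fraction `r_1+V(L)`
divides the concentration of complexes in which a monomer abuts an `L`-mer
by the total `L`-mer concentration.  The product-length indicator uses the
measured `L_U` by default (a switch selects the lower bound `L_U_min`; the
two coincide for the example genome).

Sweep utilities locate efficiency optima (log-grid at 8 points per decade
plus bounded golden-section or Nelder–Mead refinement, with the ≤1%
sub-optimality window reported for 1-D sweeps) and crossing concentrations of
`r_1+V` curves (log-grid bracketing plus bisection).

### Degenerate optima

In the tetramer/octamer two-length pool the efficiency is monotone
*decreasing* in the tetramer concentration at fixed octamer concentration:
harmful tetramer channels scale linearly in `c(4)` while the only helpful
channel (correct 4|4 ligation on an octamer template) scales quadratically,
so no interior optimum exists toward `c(4) -> 0` and the supremum sits on a
flat shoulder.  The two-length optimizer therefore supports a declared
plateau rule: efficiencies within `eps = 1e-6` — the accuracy to which the
equilibrium solver determines observables — are treated as ties, and the
largest tetramer concentration on the tied plateau is reported.  For a
genuine interior optimum the rule is neutral.

## Stochastic kinetics

The Gillespie simulator evolves explicit molecules (sequences laid out on
two rows, bottom strands 5'→3' left-to-right, top strands antiparallel;
a complex and its 180° rotation are one species).  Moves:

* association of any two molecules at any valid relative placement, each
  placement at `k_enc/(N_A V)` in count units;
* dissociation into any two connected sub-assemblies at
  `k_off = k_enc c° exp(dG/kT)`, the detailed-balance partner of the
  corresponding association placement;
* ligation at nicks (`k_lig`, optionally split monomer/oligomer).

Initial ensembles hold every genome-compatible sequence of each pooled
length at equal counts, rounded to integers at the chosen volume; the
realized (post-rounding) concentrations are recorded so that comparisons
against the deterministic solver are made at the concentrations actually
simulated.  Runs are reproducible under a fixed seed.

Equilibration is detected by fitting `A exp(-t/tau*) + B` to the total
hybridization energy `dG_tot(t)` (`tau_eq = 5 tau*`); the correlation time
comes from an exponential fit to the post-equilibration autocorrelation.
Because actual ligation events are vanishingly rare at realistic `k_lig`,
observables are estimated from the occupancy of ligation-competent complexes
in decorrelated snapshots — at the sequence level, product correctness is
decided by explicit genome membership of the ligated sequence, which makes
the stochastic route an independent check of the combinatorial `p_corr`.
Ratio estimators propagate uncertainty with the full three-term Gaussian
formula including the covariance.

### Problem sizes

Productive complexes at the reference pool concentrations occupy only
~1e-12–1e-11 M, so resolving yield at those conditions requires of order
1e9–1e11 events, i.e. days of serial compute.  The test suite instead validates the stochastic–deterministic
agreement through three scaled runs, all within 3σ:

* a two-species closed-form check (two complementary hexamers against the
  mass-action quadratic);
* the total hybridization energy — a direct functional of the full complex
  occupancy — at a reference pool condition (0.1 mM monomers, hexamers at
  ratio 3.3e-2) in a 0.02 µm³ volume;
* the complete yield/fidelity/efficiency estimator chain on a concentrated
  hexamer pool (1e-4 M), where productive complexes are abundant enough to
  sample in about two minutes.

At these volumes species hold only a few copies each, so finite-size
corrections of order 1/N are visible in the mean energies; they remain well
inside the statistical bands and shrink with volume as expected.

## Scaling laws and calibration

Closed-form approximations describe the numerics in the weak-binding,
few-strand regime: the optimal free-strand concentration ratio decays as
`sqrt(1/Lambda_FF - 1/L_V) exp(-|gamma| L_V / 2)`; the maximal efficiency
shortfall is that expression times `eta0 L_V`; with dimer feedstock an upper
efficiency bound follows from the competition of correct and false
monomer/dimer extensions; under kinetic suppression the `r_1+V` plateau is
`(1/6)(c°/Kd1 + 1 - 2Kd1/(3c°)) c1/c°` with `Kd1 = c° exp(gamma/2)` (binding
a monomer flush into a recessed duplex end gains a nick block `gamma` but
costs the template's dangling end `gamma/2`), and the half-saturation VCG
concentration scales as `exp(-|gamma| L_V)`.  The constants `Lambda_FF`,
`eta0`, the ratio amplitude and the `K`-prefactors are calibration
constants: they are fitted to the equilibrium pipeline by least squares on a
log scale over a training range of oligomer lengths and validated on
disjoint lengths.  The numerics are always the reference, never the reverse.

## Genome design

Genomes with prescribed `(L_E, L_U)` are sampled by Metropolis–Hastings with
the motif entropy `S(L) = -sum f_i log4 f_i` as Hamiltonian (base-4 logs make
the exhaustive-regime bound `S_max(L) = L` exact).  Moves are single-base
mutations and circular segment cut-and-paste (10× more likely; segment length
and insertion point uniform — the least-informative choice).  Maximally
diverse genomes minimize `-S(L_E_max) - S(L_U_min)`; intermediate motif
structure is tuned by minimizing `sum_{L_E..L_U} S(L)` from a diverse start.
Acceptance is standard Metropolis: downhill always, uphill with
`exp(-beta dH)`.  The exposed default `beta = 1e-5` makes the walk
effectively free and relies on the stop rule; the fixtures and tests use
`beta = 1e5` (quasi-greedy, plateau moves still accepted), which converges
reliably for 16- and 64-nt genomes within the default 10,000 steps.
Samplers are seed-deterministic and return the best-so-far genome with a
`converged` flag when the target scales are not reached.

## What the synthetic conditions do and do not show

All quantitative checks run on unbiased pools of an idealized circular
genome with a two-parameter nearest-neighbor energy model.  Real sequences
have sequence-dependent stacking energies, tolerate (especially terminal)
mismatches, stack across nicks more stably than this model assumes, and can
self-fold; none of these enter here.  Passing tests therefore demonstrate
internal consistency of the coarse-grained combinatorics, the equilibrium
closure and the stochastic dynamics — not quantitative agreement with any
particular experimental chemistry.

## Known limitations

* Complexes are capped at four strands in both routes by default; at strong
  binding or high concentrations larger complexes would matter.
* The duplex/2-2 symmetry factor ½ (and the stochastic pairing of a
  self-complementary strand with its own copies) ignores palindromic
  realizations; the effect is at the sub-percent level for the bundled
  genome.
* The coarse multiplicity formula assumes motif-unbiased genomes; for
  designed genomes with `L_U > L_U_min` it is approximate between the two
  scales (correctness probabilities are capped at 1 accordingly).
* Open-system influx/outflux, temperature cycling and explicit activation
  chemistry are out of scope; activation enters only through the split
  ligation rates.
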