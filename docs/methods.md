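# Methods

This note records the models implemented in `alchevo`, the numerical choices
behind them, and what the synthetic-data validation does and does not
establish. Units throughout: energies kJ/mol, distances nm, angles radians,
temperatures kelvin, branch lengths expected substitutions per codon
(k_B = 0.0083144621 kJ/mol/K; default temperature 277 K, the habitat
temperature of the motivating rainbow trout system).

## Thermodynamic cycle

The absolute binding free energy of a ligand is assembled along a closed
cycle: restrain the bound ligand, alchemically decouple its electrostatic
and Lennard-Jones interactions inside the complex, release the restraints
analytically into the standard-state volume, recouple the ligand in
solution, and correct for the simulation-box versus standard-state volume.
`assemble_cycle` treats the component legs as labelled inputs with an
explicit direction flag ("insertion" = interactions being turned on,
"deletion" = turned off) and a declared cycle sense: a leg recorded in the
declared sense contributes its value, the opposite sense contributes the
negated value, and reversing the declared sense negates the total exactly.
This makes the bookkeeping auditable when a study reports both directions.
The assembler does not require a fixed leg inventory (published tables often
collapse the two solution legs into one recoupling row); callers that want a
strict four-leg cycle pass `required=ALCHEMICAL_LEG_NAMES`.

The insertion/deletion consistency diagnostic compares the totals assembled
from the two alchemical directions on a common (insertion-sense) scale and
passes when the absolute discrepancy is at most 2 pooled standard errors.
The factor 2 is a package default — the nominal coverage of the rule under
honest error bars is 95.45% — and is configurable.

## Thermodynamic integration

`ThermodynamicIntegration.fit(method="trapezoid")` applies the trapezoid
rule to the per-λ sample means over the sampled interval, with the standard
error propagated through the quadrature weights. This is the baseline the
regression estimator improves on for sparse schedules.

`fit(method="polynomial")` fits an unweighted least-squares polynomial to
the per-λ means and integrates it analytically over [0, 1]. The degree is
chosen by leave-one-out cross-validation over degrees 1–6 (computed exactly
via the hat-matrix identity; ties resolved toward the lower degree), unless
a fixed degree is supplied. Degree selection guards against overfitting the
11- and 21-point schedules typical of alchemical work. The standard error is
a residual bootstrap: residuals of the means around the fitted curve are
resampled with replacement onto the fitted values and the integral is
re-evaluated (a linear map, so the 1000 seeded resamples are cheap). With a
single sample per λ and no noise the bootstrap standard error is 0, as it
should be.

## Bennett acceptance ratio

For forward works W_F (A→B) and reverse works W_R (B→A), the estimate
solves Σᵢ f(β(W_F,i − ΔF − M)) = Σⱼ f(β(W_R,j + ΔF + M)) with f(x) =
1/(1+eˣ) and M = k_BT ln(n_F/n_R); the equation follows from the Crooks
fluctuation relation and is the minimum-variance two-state estimator. The
residual is strictly increasing in ΔF, so the root is found by deterministic
bisection to an interval width of 1e-10 kJ/mol, bracketed by
[min − 10 k_BT, max + 10 k_BT] of the pooled works; if the distributions
barely overlap the bracket is widened with a warning and the best root is
still returned. The variance is Bennett's asymptotic expression evaluated
from the Fermi weights at the solution. A ladder of intermediate states
(e.g. growing restraint force constants through 0, 25, 40, 60, 90, 150,
200, 300, 450, 700, 1000) sums adjacent-pair estimates, with the standard
errors combined in quadrature; mixed rung temperatures are an error, never a
silent conversion.

Equilibration is handled by `discard_equilibration(data, fraction)`, which
keeps the last ceil((1−fraction)·n) samples per state — ties resolve toward
keeping more data — mirroring the common practice of discarding the first
half of each simulation.

## Restraint release and standard state

Six harmonic restraints (one distance r, two angles θ_A, θ_B, three
dihedrals) anchor the decoupled ligand. In the stiff-spring regime the
release free energy into the standard-state volume V° = 1.660539 nm³ (one
molecule at 1 mol/L) is

ΔG = k_BT ln[ 8π² V° √(K_r K_θA K_θB K_φA K_φB K_φC) /
              (r² sinθ_A sinθ_B (2π k_BT)³) ],

positive for stiff restraints. Zero force constants and degenerate angles
are rejected (the formula diverges); a floppy-regime warning fires when any
Gaussian width exceeds a quarter of the distance to the relevant boundary.
The Monte-Carlo oracle (`synth.mc_restraint_oracle`) importance-samples the
six coordinates from the exact harmonic Gaussians and corrects with the
geometric Jacobian r² sinθ_A sinθ_B, giving the anharmonically exact
integral with a delta-method standard error; at K = 1000 the closed form and
the oracle agree well inside 0.1 kJ/mol, and the residual difference is the
anharmonic correction, which shrinks as the force constants grow.

The volume term is k_BT ln(V_sim/V°), positive when the simulation box is
larger than the standard-state volume and antisymmetric under swapping the
volumes. Published volume corrections can equally be consumed as direct
inputs when the volumes behind them are not reported.

## Codon selection analysis

Codon alignments are built by threading unaligned coding sequences through
their aligned proteins (each amino-acid column maps to one codon; protein
gaps become codon gaps; a trailing stop codon is tolerated and dropped;
translation mismatches are reported with the offending position). Columns
containing gaps or ambiguous codons are removed before likelihood
computation, the cleandata convention.

The substitution model is the Goldman–Yang codon model over the 61 sense
codons: q_ij = 0 for multi-nucleotide changes, otherwise π_j times κ for
transitions and ω for nonsynonymous changes, with each branch class's
generator scaled to mean rate 1 so branch lengths are expected
substitutions per codon. Codon frequencies follow the empirical F3x4
convention (positional nucleotide frequencies, renormalized over sense
codons, floored at 1e-8 to keep the spectral decomposition defined) and are
not counted as free parameters. The chain is time-reversible, so transition
matrices exp(Qt) come from one symmetrized eigendecomposition per (κ, ω)
class, making repeated likelihood evaluations cheap.

Likelihoods use Felsenstein pruning with site-pattern compression (exactly
value-preserving) and per-node rescaling against underflow; gap codes
marginalize as fully ambiguous states. Trees are unrooted with a
trifurcating storage root; rooted Newick inputs are unrooted on parse.
Neighbor joining follows Saitou–Nei with a deterministic tie-break (lowest
index pair on equal Q) and negative branch-length estimates clamped to 0,
on Jukes–Cantor-corrected nucleotide distances (gapped positions skipped;
saturated pairs capped at 5 substitutions/site with a warning).

A branch hypothesis partitions the 2N−3 edges into ω classes by edge
selectors (taxon sets identifying terminal branches or clades); the
parameter count is k = (2N−3) + 1 + (number of classes). Fitting maximizes
the likelihood over branch lengths (initialized from the NJ tree, bounded
[0, 20]), κ ∈ [0.1, 20] and ω ∈ [1e-4, 10] with L-BFGS-B, using 3 starts:
the first from (κ=2, ω=0.2), the rest with seeded log-normal jitter on
(κ, ω). Explicit starts can be supplied, which is also how nested-model
comparisons share a starting point. Models are ranked by full-precision
AIC = 2k − 2ℓ with ties broken by smaller k then hypothesis id; reports
round AIC to the nearest integer, the convention of the published table
(verified consistent with all five of its rows).

## Synthetic data and what it shows

All generators are deterministic given a seed, record their truths in
machine-readable form, and emit the same plain-text formats the readers
consume. `ScenarioSeeds` derives independent per-stage streams from one
scenario seed so adding a stage never perturbs earlier draws.

- `gen_dhdl` draws i.i.d. Gaussian noise around a polynomial mean curve. It
  does not mimic the autocorrelation of real simulation time series, so the
  recovery tests validate the quadrature and the bootstrap, not
  decorrelation practice.
- `gen_bar_works` draws the Gaussian work pair that satisfies the Crooks
  relation exactly: W_F ~ N(ΔF + βσ²/2, σ²), W_R ~ N(−ΔF + βσ²/2, σ²).
  Real work distributions are rarely Gaussian; the tests establish estimator
  correctness and asymptotic behaviour (bias shrinking with n), not
  robustness to heavy-tailed work.
- `simulate_codon_alignment` evolves sites independently (no indels, no
  among-site rate variation) under the exact fitted model family, so
  recovery studies measure estimation error, not model misspecification.

The packaged selection-contrast scenario fixes an 8-taxon tree whose focal
terminal branch carries 0.35 expected substitutions/codon against
background branches of 0.06–0.25, with background ω = 0.09, focal ω = 0.30,
κ = 2, uniform codon frequencies and 500 codons. The focal branch length is
chosen to mirror the motivating system, where the focal duplicate lineage
has accumulated substantial divergence since the salmonid whole-genome
duplication (the duplicate pair shares only ~75% amino-acid identity): a
single branch must carry enough substitutions for its own ω to be
estimable, and a near-zero focal branch would make the two-ratio contrast
statistically unidentifiable at any implementation quality. Problem sizes
in the validation suite (200 replicates for BAR/TI coverage, 20 replicates
for the selection contrast, 5×10⁵ Monte-Carlo samples for the restraint
oracle) are the package's chosen balance of statistical resolution against
runtime on a single CPU.

## Known limitations

- No multistate estimator (MBAR) and no trajectory-level processing; the
  package starts from sampled ∂H/∂λ and work values.
- TI's polynomial regression fits the means unweighted; strongly
  heteroscedastic λ-schedules would motivate a weighted variant.
- The restraint formula assumes the stiff-spring regime; the package warns
  rather than switching to numerical integration automatically.
- Branch models only: no site-heterogeneous or branch-site (positive
  selection) classes, no tree search beyond neighbor joining, no codon-level
  alignment inference (alignments are inputs).
- Real-sequence results (the published ω values 0.09/0.30/0.07 and the
  identity percentages) require the original sequence data and are bundled
  as flagged inputs, not recomputed.
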