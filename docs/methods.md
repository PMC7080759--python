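# Methods

## The protective index

Defensive symbionts are usually scored by host survival alone. Survival is
an incomplete currency: hosts that survive parasitoid attack can be partly
sterilised, produce fewer offspring, and be smaller. The protective index
(PI) used here is the ratio of the product survival × p(fertile) × mean
daughters of fertile females between wasp-exposed and unexposed
symbiont-carrying hosts,

    PI = (s_e f_e m_e) / (s_u f_u m_u).

Both sides condition on symbiont carriage; the index measures what fraction
of an unattacked host's reproductive output an attacked, symbiont-protected
host retains. It assumes near-complete mortality of symbiont-free hosts
under attack (observed: <1% survival), so the symbiont-free arm enters the
analysis only as a diagnostic, never as a PI.

The point estimate is the plug-in ratio of the six group summaries — not a
posterior mean — so that feeding a results table's printed summaries into
`compute_pi` reproduces the table's printed index exactly.

### Uncertainty propagation

Credible intervals come from Monte Carlo simulation:

* each proportion (survival, fertile) gets a conjugate Beta posterior
  Beta(α₀ + k, β₀ + n − k); the prior defaults to uniform Beta(1, 1), with
  Jeffreys (½, ½) available — the distributional family is the modelling
  commitment, the hyperparameters a documented default;
* each mean fecundity gets a Normal(mean, se) posterior truncated at zero
  (truncation prevents sign-flipping PI draws and matters only when the
  mean is within ~2 se of zero);
* the six draws are independent — no attempt is made to model correlation
  between survival, fertility and fecundity of the same flies — and are
  combined into one PI draw each; the 2.5th/97.5th percentiles of 100,000
  draws give the equal-tailed 95% interval (percentile Monte Carlo error
  < 0.002 at that size; a warning is raised below 1,000 draws).

Posterior strain comparisons pair draws by index:
P(PI_a > PI_b) = (#{a_i > b_i} + ½ #ties) / n, so
P(a > b) + P(b > a) = 1 exactly.

### The survival-only bound

When survivor fertility cannot be assayed (the Lh14 strain leaves too few
survivors), the reproductive factors can only shrink the index, so survival
information bounds PI from above. Two conventions exist in circulation for
this bound: the survival *ratio* s_e / s_u (consistent with the index's
definition as a ratio of products) and the survival *product* s_e · s_u.
The published bounds for Lh14 (<0.036 without ethanol, <0.007 with) equal
the product of the two survivals, while the accompanying text describes the
bound only as "less than the survival value". This package defaults to the
ratio convention and exposes the product convention behind a flag; neither
is asserted as ground truth, and bounds are always flagged as bounds, never
mixed with estimates.

### Reconstructed counts

Results tables print proportions, not raw counts. For credible-interval
work the package reconstructs integer (successes, total) pairs whose
fraction is closest to the printed proportion, searching totals within ±10
of the stated design sizes (~450 larvae per survival cell from 12–15 vials
of 30; ~45 females per fertility cell). This is an approximation by
construction — printed values carry two decimals — and the pipeline logs
the sample sizes actually used so the approximation is auditable. With
default priors the reconstructed interval for the Lh-Fr/no-ethanol index is
(0.126, 0.328) against a published (0.12, 0.33).

## Inferential layer

Assay responses are modelled with standard GLMs: vial-level binomial for
fly survival and wasp emergence (successes/totals with vial totals as
variance weights — likelihood-identical to per-larva Bernoulli rows),
Poisson for oviposition counts, Gaussian linear models for daughter counts
and Box-Cox-transformed wing areas.

Term tests are marginality-respecting (Type II) likelihood-ratio tests: a
term is tested by comparing the model containing every term that does not
contain it, with and without the term. A main effect is therefore never
removed while its interaction remains in either fitted model. Binomial and
Poisson families use χ² on the deviance difference; Gaussian models use F
tests with the full model's residual mean square in the denominator.
Stepwise simplification repeatedly removes the least-significant removable
term with p > α (default 0.05) — interactions become removable before the
main effects they contain — with an alphabetical tie-break so the
simplification path is deterministic.

Wasp-emergence data exhibit complete separation (symbiont-positive vials
produce zero wasps, always), under which unpenalized logistic ML estimates
are infinite — the estimate grows without bound as the IRLS iteration cap
is raised. The separation-robust fit is maximum a-posteriori logistic
regression with independent Cauchy priors on internally standardized
predictors (binary design columns centered; continuous columns scaled to
sd 0.5; prior scale 2.5 on coefficients, 10 on the intercept), optimized by
multi-start BFGS with analytic gradients. This yields finite,
start-independent estimates (agreement to 10⁻⁶ across starts) and matches
an independent profile-grid maximization of the log posterior. Symbiont
interaction terms are excluded from the wasp-emergence model by
configuration, since every symbiont-positive cell is all-zero. Full
posterior sampling is deliberately out of scope: the fit exists to provide
finite estimates under separation, nothing more.

Box-Cox exponents are estimated by profile likelihood on a fixed grid
([−2, 2] in steps of 0.01) rather than by continuous optimization, so the
estimate is deterministic and exactly reproducible; y = (x^λ − 1)/λ with
the natural log at λ = 0.

## Wing morphometrics

Wing area — a body-size proxy reflecting developmental stress — is the
absolute shoelace area of the hexagon through six landmarks supplied in
boundary order, divided by the squared per-image pixels-per-mm scale.
The area is invariant to translation, rotation and point-order reversal and
scales quadratically under coordinate scaling. Degenerate inputs are
handled explicitly: duplicate consecutive landmarks collapse an edge
(allowed), fewer than three distinct points give zero area with a warning,
and self-intersecting orderings give the absolute signed area with a
warning (real assays exclude unclear landmark sets rather than repair
them). The six landmarks are treated as an opaque ordered hexagon; no
Procrustes/shape analysis is attempted.

## The synthetic experiment

The generator emulates the statistical structure of the factorial assay so
every downstream stage is testable without external data: three wasp-strain
blocks, each crossing exposure × symbiont × ethanol; 12 vials × 30 larvae
per treatment cell (the reported range is 10–15 vials); ~45 females per
fertility cell; Poisson oviposition with rate 1.4 (realised means between 1
and 2). Default cell parameters equal the summary statistics of the
original experiment; summaries reported only as bounds use the bound's
midpoint, and cells never measured (fertility of symbiont-free or
Lh14-attacked survivors, Lh14 wings) are generated as absent, which
exercises the analysis layer's bound-only mode.

Generative choices worth knowing:

* survivors per vial are binomial by default; a beta-binomial with
  intra-vial correlation `icc` (between-vial variance inflated by
  1 + (n−1)·icc) is available for robustness testing only, since the
  inferential layer fits plain GLMs;
* pupation is layered on top of survival (conditional rate among
  non-survivors), so count orderings hold by construction; wasps emerge
  binomially from pupated non-survivors and never from symbiont-positive
  cells;
* daughter counts are zero-truncated rounded normals whose *location is
  calibrated so the realized mean equals the configured mean* — naive
  truncation would bias cells where the sd is comparable to the mean (e.g.
  5.45 ± 6.5) upward by more than 2 daughters; totals are split across the
  four assay days by a symmetric multinomial;
* per-female fecundity SDs are back-calculated from the printed standard
  errors and the implied number of fertile females;
* wing records are regular hexagons whose area equals a normal draw
  (per-female SD 0.07 mm², matching printed SEs at n ≈ 100), randomly
  rotated and translated at a fixed 200 px/mm scale;
* male-killing is implicit: symbiont-positive survivors are all female, no
  sex field is generated, and no analysis uses sex;
* one global seed derives independent named substreams per table, so
  regenerating one table never perturbs another, and every generated file
  is byte-reproducible given the seed.

What the generator does **not** emulate: within-host dynamics (symbiont
titre, wasp development time), vial-to-vial environmental drift beyond the
optional beta-binomial, day-structure in laying beyond the symmetric split,
and measurement error in landmark placement. Passing tests therefore show
that the analysis recovers the configured outcome distributions, not that
real data meet those distributional assumptions.

## Scale of the shipped checks

Test and acceptance runs use sizes chosen to keep Monte Carlo error well
inside the asserted tolerances: 10³–10⁴ vials for law-of-large-numbers
checks, 30–40 replicate study-scale experiments for recovery and power
checks, 150 replicates for type-I calibration, and 2 × 10⁴–10⁵ posterior
draws. One caveat found while calibrating: under the default (study-scale)
parameters the symbiont × strain survival interaction test has only ~75%
power at α = 0.05, because symbiont-free cells contain ~2 survivors each
and carry almost no information; the power property is therefore
demonstrated on a strongly-interacting configuration with baselines away
from the boundary, and the study-scale figure is stated here as a finding.

## Known limitations

* PI treats its six components as independent; within-fly correlation
  between surviving attack and subsequent fertility is not modelled.
* Credible-interval reproduction from printed tables is approximate:
  exact per-cell sample sizes are unknown and proportions carry two
  decimals.
* The survival-only bound's convention (ratio vs product) is genuinely
  ambiguous in circulation; both are provided, the ratio is the default.
* No overdispersion or random-effect models are fitted; the beta-binomial
  lives only in the generator.
* Real assay data are accepted only through the documented CSV schemas;
  externally deposited raw files must be normalized into them first.
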