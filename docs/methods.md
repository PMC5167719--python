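# Methods

## Scope and model chain

The package links three layers:

1. **Allele → parameter**: a purely additive linear genetic model on 31
   biallelic loci (0 = wild D allele, 1 = cultivated S allele). No
   dominance, no epistasis, no QTL×environment terms. Intercepts describe
   the all-D genotype, so every effect is the marginal change from carrying
   the S allele at that locus.
2. **Parameter → phenotype**: a process-based simulation of fruit dry mass,
   stone ratio and flesh sugar concentration over a fixed 87–150
   days-after-bloom (DAB) window.
3. **Phenotype → ideotype**: three-objective minimization of
   `(−DM, SR, −SU)` with NSGA-II over four nested search spaces (observed
   parameter box, genetically attainable box, free allele space,
   linkage-constrained allele space).

A synthetic-progeny layer closes the loop in the other direction
(phenotype kinetics → fitted parameters → re-estimated allele effects) so
the whole estimation chain is testable without field data.

## Fruit model and its closure

The printed equations cover potential dry-mass growth (logistic in thermal
time), stone allometry, and the sugar-carbon balance. The original
carbon-supply machinery (leaf photosynthesis from SLA-dependent leaf area,
reserve mobilization, water flows, Lockhart growth) is *not* reproduced;
it is replaced by a declared demand-driven closure:

* realized growth equals the logistic potential;
* the flesh carbon supply covers structural carbon plus growth
  respiration: `F_Csupp = (α+β)·dDM_flesh/dt`, so the Eq.-3 partition
  `1 − α/(α+β)` leaves exactly `β·dDM_flesh/dt` entering the sugar pool;
* fresh mass is closed by a constant flesh dry-matter content:
  `FM_flesh = DM_flesh / dmc`;
* an optional hook (`sla_ref`) multiplies growth by `min(1, SLA/SLA_ref)`
  for source-limitation studies. It is off by default, which is why SLA
  deliberately has no influence on the three traits in the default
  configuration — mirroring the low observed sensitivity of the traits to
  SLA.

The logistic numerator is read as `A·DM0^B` (both parameters "involved in
the asymptote"); the alternative product reading `A·DM0·B` is available via
`GrowthConfig(asymptote_mode="product")`.

### Constants, units, defaults

| constant | default | unit | why |
|---|---|---|---|
| `DM0` | 13 | g | dry mass of a mid-season cultivated peach at 87 DAB; also the smallest scale at which the stone allometry leaves positive flesh over *every* declared search-space corner (worst case Wstone·kstone ≈ 4.87 in the observed box) |
| `dj0` | from weather | GDD | thermal time at 87 DAB (1305 GDD under default weather) |
| `alpha` | 0.08 | gC/gDM | growth respiration coefficient, peach-scale literature value |
| `beta` | 0.44 | gC/gDM | carbon content of fruit biomass |
| `ksugar` | 0.05 | day⁻¹ | relative conversion of sugar carbon to non-sugar compounds; genotype-independent here |
| `sigma_ts` | 0.42 | gC/g | mean carbon content of sucrose/glucose/fructose/sorbitol |
| `dmc` | 0.15 | g/g | flesh dry-matter content closing fresh mass |
| `f0` | 0.5 | – | initial sugar fraction of flesh carbon, sets `Csugar(t0)` |
| weather | constant 22 °C, base 7 °C | – | an Avignon-like summer mean; 15 GDD/day, so the window spans 1305–2250 GDD |

None of the acceptance targets depends on these constants; they shape the
phenotype landscape that the optimization and dominance studies explore.
With these defaults the all-wild genotype yields DM ≈ 52 g (dry), SR ≈
0.07, SU ≈ 4.8 g/100 g — a plausible large peach.

### Numerics

* Dry mass and stone curves are closed-form; logistic exponents are clipped
  at ±700 so extreme parameter corners saturate instead of overflowing.
* The sugar ODE is solved by classic fixed-step RK4 on a daily grid
  (`step` configurable; must divide the window). For the linear ODE with
  constant supply RK4 preserves the steady state exactly; on smooth
  manufactured solutions the observed convergence order is ≥ 3.5. A
  negative solution (possible only with pathological supply/step choices)
  raises rather than silently clipping.
* Batch simulation is fully vectorized across individuals, which makes the
  exhaustive enumeration of all 2^17 linkage-feasible genotypes (~131k
  simulations) run in seconds — that enumeration is the brute-force oracle
  for the optimizer.

## Genetic model handling

* Per-parameter bounds are computed analytically: effects are additive and
  independent, so each extreme is attained by the sign-determined genotype.
  The recomputed bounds match the published restricted-space table except
  the kstone minimum, where the printed coefficients sum to 0.05462 against
  a printed 0.05448 (Δ≈1.4e-4, coefficient rounding). The package reports
  the recomputed value.
* Haplotype blocks are the union-find transitive closure of the 14
  inseparable pairs: 8 multi-locus blocks plus 9 singletons, 17 free
  dimensions. Block order is deterministic (by smallest member), so block
  encodings are stable across runs.
* Allele-effect estimation is joint ordinary least squares per parameter
  (intercept + the parameter's loci). Whether the original effects were
  estimated marginally or jointly is not documented; joint OLS is the
  natural reading of a linear-model fit and is what the package implements.
  Rank-deficient designs raise an error naming the collinear loci instead
  of silently pseudo-inverting — perfect linkage is an identifiability
  problem the user should see.

## NSGA-II

Standard elitist (μ+λ) NSGA-II: fast non-dominated sorting (O(MN²)),
crowding distance with all extreme-attaining individuals treated as
boundaries (+∞) — this makes the distance order-independent under ties —
binary tournaments on (rank, crowding, uniform random), SBX (η=20) +
polynomial mutation (η=10, p=0.1) for continuous decisions, single-point
crossover + per-bit flips (p=0.01) for binary ones; crossover probability
0.9, population 100, 250 generations.

Design choices the published description leaves open:

* **Constraint handling** (linkage): default is reparameterization — the
  optimizer works on the 17 block bits and decodes to 31 loci, so every
  candidate is feasible and the exhaustive oracle is enumerable. The
  alternative (`constraint_mode="constraint_domination"`) optimizes all 31
  bits under Deb's feasibility rule with the number of split pairs as the
  violation; both modes end feasible.
* **Archive semantics**: reported "distinct individuals" counts exceed the
  population size, which is only consistent with accumulating rank-1
  solutions across generations. The default archive therefore collects the
  distinct non-dominated union over all generations (exact decision-vector
  equality for binary, 1e-12 relative componentwise for continuous);
  `archive_mode="final_population"` restricts to the last generation's
  first front. Published archive cardinalities are treated as qualitative,
  not as test targets.
* Initialization is uniform in the box / i.i.d. fair bits; all randomness
  flows from one seed, and equal seeds give bit-identical results.

Hypervolume (for oracle comparisons) is computed exactly for 2-d/3-d
minimization fronts by sweeping the third objective over 2-d staircase
areas; the reference point for the oracle test is the enumerated front's
nadir plus 10% of its range, fixed before any optimizer run.

## Synthetic progeny

The generator emulates the structure of the real backcross progeny, not its
data:

* **Genotypes**: one Bernoulli draw per haplotype block (expected D
  frequency 1/4), blocks independent, loci within a block identical. Real
  within-block recombination (rare but nonzero) is not simulated; a
  consequence is that loci 23 and 26 — both in block {23,24,25,26} and both
  affecting parameter A — are perfectly confounded, so only their summed
  effect is identifiable and the estimation report works with that sum.
* **Parameter values**: genetic prediction plus additive Gaussian noise,
  calibrated per parameter so the genetic share of the variance equals
  `variance_explained` (default 0.30 for every parameter, the midpoint of
  the reported 10–50% range). Rare draws producing non-positive parameters
  or a stone allometry that exceeds the smallest simulated fruit are
  redrawn (≈1–2% of draws); this truncation is the price of keeping
  Gaussian noise on strictly positive quantities.
* **Kinetics**: three fruits per individual at staggered initial masses
  (0.8/1.0/1.2 × DM0 — multiple fruit per genotype is what makes A and B
  separately identifiable, since a single curve only constrains `A·DM0^B`),
  sampled weekly (10 dates), with i.i.d. Gaussian observation noise per
  trait (defaults: 0.5 g on DM, 0.01 on SR, 0.3 g/100 g on SU — a
  well-measured field trial). SLA does not move the traits, so it is
  "measured" directly with small Gaussian noise, as leaf measurements would
  be.
* **Fitting**: bounded multi-start (≤8 starts, early-stopped when restarts
  stop improving) trust-region least squares with analytic Jacobians; the
  growth fit shares (A, B, RGRini, P3) across fruits with per-fruit initial
  masses as nuisance parameters; the stone fit uses (DM, DM·SR) pairs.
  Fit boxes are deliberately wider than any search space so noisy truths
  near the observed extremes are not clipped. Individuals that fail to
  converge are flagged and excluded with a count.

What a green recovery test does and does not establish: it shows the
estimation chain is consistent (noiseless data are inverted exactly; at the
stated noise the mean recovered effect of every identifiable term sits
within Monte-Carlo error of truth across 20 replicates). It does not show
the fits are efficient — per-individual A and P3 estimates are genuinely
noisy because the inflection point often lies beyond the observation
window, exactly the regime where the original analysis needed mixed-effects
shrinkage (out of scope here, replaced by per-individual least squares).

## Known limitations

* The fruit biophysics is a closure, not the full source-driven model; SLA
  is inert by default and absolute SU values depend on `dmc`, `f0`,
  `ksugar` choices.
* One weather series and one configuration per study run; no
  genotype×environment exploration.
* Linkage is all-or-nothing (inseparable vs independent); no probabilistic
  recombination distances.
* Published dataset cardinalities (how many distinct optimized individuals
  a run reports) depend on archive semantics the source leaves unspecified;
  they are reproduced in order of magnitude only.
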