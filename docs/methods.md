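# Methods

`centroevo` models the early evolution of newly formed tetraploid cell
populations: how the supernumerary centrosomes created by cytokinesis
failure are lost from the population over days-to-weeks while the doubled
genome is retained. This note records the models, their assumptions, the
defaults, and the numerical and design choices.

## Chromosome partitioning in multipolar divisions

A k-ploid mitotic cell (k replicated copies of each of M nonhomologous
chromosomes; k = 4, M = 23 for a human tetraploid) that divides with
p > 2 spindle poles distributes its genome unevenly. The model makes two
assumptions: (i) sister chromatids never co-segregate — each sister pair
splits between a uniformly random unordered pair of distinct poles — and
(ii) chromosome types partition independently. Chromosome missegregation
in bipolar divisions is ignored.

Under these assumptions, for one fixed daughter cell and one chromosome
type:

- P(nullisomy, 0 copies) = ((p−2)/p)^k,
- P(monosomy, exactly 1 copy) = 2k(p−2)^(k−1) / p^k,
- the two events are mutually exclusive, so the combined probability is
  their sum.

The probability that a daughter suffers the event for *at least one* of
its M independent chromosome types is 1 − (1 − q_event)^M, and the number
of affected chromosome types is Binomial(M, q_event). The per-chromosome
binomial parameter is written `q_event` throughout because the population
model uses the bare symbol q for an unrelated probability (normal
division of a normal cell); the collision is in the source literature's
notation, not ours.

Two caveats worth recording. The per-pole perspective means no factor of
p for the choice of daughter is applied. And the degenerate case k = 1,
p = 2 gives monosomy probability 2·0⁰/2 = 1 — correctly: a haploid
mother's single pair splits 1:1, so each pole holds exactly one copy.
"Bipolar divisions missegregate nothing" therefore holds for k ≥ 2 only.

Correctness is established two ways: an exact oracle that enumerates all
C(p,2)^k sister-pair assignments in rational arithmetic (`fractions.
Fraction`; equality with the closed forms is exact, not approximate, for
all k ≤ 4, p ≤ 4), and a Monte-Carlo partition simulator checked to
within four binomial standard errors at 10^5 draws.

## Population dynamics of centrosome classes

Cell types are labelled by mitotic centrosome number: C2 (normal), C4
(doubled), C6 (tripled), and — in the extended model — SC
("super-clustering") cells, C4 cells that cluster their extra
centrosomes with near-perfect efficiency and so behave like normal cells.

Per-division fate rules (probabilities), shared by the deterministic and
stochastic engines:

- a C2 division is normal with probability q; otherwise cytokinesis
  fails and yields a single binucleate daughter with doubled
  centrosomes (an SC cell with probability v in the extended model);
- a C4 cell clusters into a bipolar spindle with probability p_bipolar;
  the bipolar division is symmetric (C4 + C4) with probability r,
  otherwise asymmetric 3:1 clustering yields C2 + C6;
- a multipolar C4 division leaves at most one viable C4 daughter, which
  survives with probability fs (a single combined parameter);
- SC cells divide symmetrically (SC + SC) with probability r_S,
  otherwise asymmetrically (C2 + C6), at the rates of normal cells;
- C6 cells never divide viably and are removed at rate d_C6.

With division rates b_i and death rates d_i (all per day — the time unit
everywhere), the expected abundances follow a linear constant-coefficient
system dX/dt = P·X. The basic model tracks (C2, C4, C6); the extended
model adds SC. Setting v = 0 with no seeded SC cells reduces the
extended model to the basic one exactly (verified to 1e-10 relative).

Named defaults `dld1` and `rpe1_p53ko` carry the measured/fitted
parameter sets of the two studied cell lines verbatim:

| parameter | DLD-1 | RPE-1 p53−/− | meaning |
|---|---|---|---|
| b_C2 | 1.2 | 0.94 | division rate of C2 and SC cells (d⁻¹) |
| b_C4 | 1.0 | 0.6 | division rate of C4 cells (d⁻¹) |
| q | 0.975 | 0.975 | probability a C2 division is normal |
| p_bipolar | 0.33 | 0.25 | probability a C4 division is bipolar |
| r | 0.5 | 0.7 | probability bipolar clustering is symmetric |
| fs | 0.4 | 0.7 | survival of the C4 daughter of a multipolar division |
| d_C2 | 0 | 0 | death rate of C2/SC cells (d⁻¹) |
| d_C4 | 0.5 | 0.12 | death rate of C4 cells (d⁻¹) |
| d_C6 | 1.5 | 1.5 | death rate of C6 cells (d⁻¹) |
| v | 0.22 | 0.32 | probability a cytokinesis-failure product is SC |
| r_S | 0.93 | 0.90 | probability an SC division is symmetric |

Day-0 compositions use the measured fractions of cells with extra
centrosomes immediately after the cytokinesis block: 90% (DLD-1) and
87.3% (RPE-1 p53−/−), i.e. alpha = 0.10 / 0.127 normal cells.

**SC seeding at day 0.** The source data do not state how many of the
day-0 extra-centrosome cells are SC. Because that population was created
by one induced cytokinesis-failure event and v is precisely the
probability that such an event yields an SC cell, the default splits the
day-0 extra-centrosome pool v : (1−v) into SC : C4. The seeding rule is
a pluggable argument (`sc_seeding="none"` starts with SC = 0), so the
assumption is testable rather than baked in.

**Extra-centrosome convention.** "Fraction with extra centrosomes"
includes C6 by default (any cell with more than one centrosome); an
`include_C6=False` switch supports the alternative reading, which is not
fixed by the source description. At the defaults the C6 fraction is
below 2%, so the choice barely moves the curves.

**Integration.** The default solver is the matrix exponential
(`scipy.linalg.expm`), exact for a linear constant-coefficient system up
to floating point; an adaptive Runge–Kutta path (DOP853, rtol 1e-10 /
atol 1e-12) is retained purely as an independent cross-check and the two
agree to better than 1e-8 relative over 12 days at the defaults.

## Steady state

Although the population grows without bound, the type *fractions*
converge. Substituting f_i = X_i/ΣX_j turns the linear system into a
nonlinear fraction ODE whose fixed point satisfies P·f = C∞·f: the
limiting fractions are the eigenvector of P belonging to its largest
eigenvalue, normalized to unit sum, and C∞ (the asymptotic per-capita
growth rate) is that eigenvalue. The implementation selects the leading
eigenpair by largest real part, fixes the sign by requiring a
non-negative dominant entry, and raises a diagnostic error if the two
largest real parts coincide within 1e-9 — a unique dominant mode is
assumed, and silently picking one of a degenerate pair would be wrong.

`verify_against_integration` confirms the eigenpair against a
long-horizon integration. Abundances at growth rate ~1.1/day overflow
long before 200 days, so the check integrates in 25-day chunks,
renormalizing to fractions between chunks (scale invariance of the
linear system makes this exact), and also compares the late-time
d(log total)/dt against C∞. It refuses to run when the spectral gap is
too small for the transient to decay below the requested tolerance at
the given horizon, rather than failing obscurely.

## Fitting and sensitivity

The fitted observable is the extra-centrosome fraction at each
observation day (default cadence 0, 2, …, 12 days, matching the
experimental design). The objective is unweighted least squares on the
fractions — the source work does not state its objective, and unweighted
LS is the assumption-lightest choice; inverse-binomial-variance
weighting is available when per-day cell counts are recorded.
Fittable parameters and their allowed ranges: v ∈ [0, 0.6],
r_S ∈ [0.5, 1], b_C2 ∈ [0.8, 1.2], b_C4 ∈ [0.6, 1], q ∈ [0.975, 1].

The optimizer is a deterministic multi-start scheme: a full grid of five
points per free dimension seeds bounded L-BFGS-B refinements and the
best local optimum wins. L-BFGS-B with numerical gradients was chosen
over a derivative-free local method because the objective — a smooth
function of matrix exponentials — is cheap and differentiable; the
multi-start grid, not the local method, is what guards against local
optima. No randomness enters the fit.

Identifiability: with seven noiseless time points, (v, r_S) is sharply
identified (recovery error < 1e-3 from any start). Under binomial
scoring noise at 300 cells/day the information content depends strongly
on where the truth lies: near the fitted values (r_S ≈ 0.9) the
Cramér–Rao bound on v is ~0.03, but for r_S ≲ 0.75 it grows to 0.06–0.36
because frequent asymmetric SC divisions make the curve nearly
insensitive to how the extra-centrosome pool is initially split. Median
recovery error over random truths is therefore dominated by r_S-low
corners of parameter space; r_S itself is always recovered to ~0.01–0.04.

Sensitivity scans evaluate either the day-12 or the steady-state
extra-centrosome fraction over a one-parameter grid with everything else
fixed, and report the monotone direction and the metric's range (used to
rank which parameter dominates). At the defaults the basic model's
steady state is non-increasing in q, and the extended model's day-12
metric responds most strongly to r_S — asymmetric SC division
(probability 1 − r_S) is the only drain on the SC pool.

## Stochastic simulators (the synthetic-data generators)

`simulate_lineages` is an exact continuous-time (Gillespie) simulation
of the cell-type counting process: each cell of type i carries
independent exponential division and death clocks at rates b_i, d_i, and
division outcomes follow the fate table above. Defaults emulate the
study's measurement conditions: initial population 5000 cells with the
day-0 composition above (multinomially assigned), 12-day horizon,
observations every 2 days, 300 cells scored per day with binomially
distributed extra-centrosome counts. Continuous time was chosen over
discrete generations so that the per-day exponential rates are used
directly, without conversion.

Culture passaging is emulated by a population cap (default 2×10⁴): every
cell beyond the cap is removed uniformly at random, which leaves the
type fractions unbiased in expectation (verified against uncapped runs)
while keeping 12-day runs tractable despite mean-field growth of
e^{~14}. One root seed drives everything; replicate r of an ensemble
uses seed root + r.

What the generator emulates: per-day extra-centrosome fractions with
demographic noise, binomial scoring noise, division-fate event logs.
What it does not: cell-cycle structure (G1 vs mitotic centriole counts),
density-dependent rates, spatial effects, imaging artefacts, or the
trinucleated-daughter phenomenon beyond the bulk fs parameter. Passing
recovery tests on these data therefore show the inference machinery is
correct under the model's own assumptions — not that the model is a
complete account of the biology.

`simulate_karyotype_evolution` attaches a per-cell replicated-karyotype
vector to the same fate machinery to emulate chromosome-spread time
courses. Bipolar divisions copy the karyotype (no missegregation);
cytokinesis failure doubles it; a multipolar C4 division draws 3 or 4
poles (default 50:50 — both occur at comparable frequency in the imaging
data and no printed ratio exists; configurable), partitions every
replicated chromosome by the sister-pair rule, and splits the four
centrosomes 2:1:1 (tripolar, one C4-like daughter) or 1:1:1:1
(tetrapolar, all C2-like). Multipolar daughters then face a mechanistic
viability rule — nullisomy lethal by default, with a configurable
survival probability when any chromosome is monosomic (default 1, since
only certain monosomies are lethal) — which *replaces* the bulk
parameter fs in this branch. Because of that substitution the karyotype
simulator is a mechanistic emulation of the chromosome-count
distributions, not a third implementation of the population model; its
population-level fractions are close to, but not bound to, the ODE.
The population starts with alpha·N0 diploid "non-responder" C2 cells
(copy number k/2) and the rest tetraploid, matching the observed
near-diploid subpopulation.

## Bespoke statistics

**Symmetry score.** For a division with p poles, each pole's share of
total DNA signal is divided by the even-split expectation 1/p and the
score is the standard deviation of the p ratios: 0 for a perfectly even
division. The population-SD convention (divisor p) is the default
because a cell's poles are its complete set of measurements, not a
sample from a larger one; the sample convention (divisor p−1) is
available via `ddof=1`. For two poles with shares (1/2 ± ε) the score is
exactly 2ε.

**Karyotype categories.** Chromosome counts are classified as
near-diploid, near-tetraploid, or highly aneuploid. The source figures
never print bin edges, so the bins are explicit, mandatory-visible
configuration with defaults 46 ± ~10% → [41, 51] and 92 ± ~10% →
[83, 101]; everything else is highly aneuploid. Every positive count
maps to exactly one category.

## Numerical and testing choices

- Tolerances: eigenvector-vs-integration agreement 1e-6 L∞ at 200 days;
  expm-vs-adaptive agreement 1e-8 relative; fraction normalization 1e-9;
  Monte-Carlo checks 3–4 standard errors at their stated sizes.
- Exact checks use rational arithmetic; nothing is asserted "approximately
  equal" where exact equality is achievable.
- Problem sizes: the agent-based/ODE consistency check uses 200
  replicates of 5000 cells over a 4-day horizon; partition Monte-Carlo
  uses 10^5 divisions; recovery studies use 20 random truths, 7 time
  points, 300 cells/day. These are the sizes at which the stochastic
  checks have comfortable power at 3–4 SE while staying at desk scale.
- Degenerate inputs raise typed, descriptive errors (zero population,
  empty extra-centrosome pool, degenerate eigenspace, too-short horizon)
  rather than returning NaN.

## Known limitations

- The linear models have no carrying capacity; only fractions, not
  absolute counts, are meaningful at late times.
- fs conflates daughter-formation and survival probabilities; the data
  cannot separate them, so neither does the code.
- The karyotype simulator's viability rule is binary in nullisomy and
  uniform across chromosomes; real monosomy tolerance is
  chromosome-specific.
- Day-0 SC seeding is an inference (see above), not a measurement; both
  seeding rules are exposed so the sensitivity of any conclusion to this
  assumption can be checked directly.
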