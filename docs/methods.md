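# Methods

## The pharmacokinetic model

All kinetics assume a one-compartment open model with first-order
absorption and first-order elimination after a single oral dose. The
plasma concentration is the Bateman double exponential

    C(t) = F D ka / (Vd (ka − ke)) · (e^(−ke t) − e^(−ka t)),

with dose D in mg, volume of distribution Vd in L (so C is mg/L ≡
µg/mL), rate constants in h⁻¹ and bioavailable fraction F ∈ (0, 1].
Closed forms used throughout: t½ = ln 2 / ke; AUC(0→∞) = F·D/(Vd·ke);
Tmax = ln(ka/ke)/(ka − ke), continuous through ka = ke where it equals
1/ke. Multi-compartment disposition, absorption lag times and saturable
absorption are out of scope.

### Inverting the peak-time relation

For fixed ke the map ka ↦ Tmax is strictly decreasing on all of
(0, ∞) — the claim is easy to verify by differentiation and is asserted
on grids in the tests — so a given (Tmax, ke) pair determines exactly
one ka. The root lies above ke (absorption-limited kinetics) if and only
if Tmax < 1/ke and below ke (flip-flop kinetics) if and only if
Tmax > 1/ke. Since a concentration curve is symmetric under swapping the
two rate constants, the data alone cannot say which regime a study is
in; the solver therefore takes an explicit branch argument, defaults to
the absorption-limited branch (FQ absorption is typically faster than
elimination), annotates every solved ka with its branch, and refuses a
branch that is inconsistent with the requested Tmax, naming the boundary
1/ke in the error. Root finding is Brent's method on log ka over the
bracket [ke(1 ± 10⁻⁹), ke·10^±6] (extended adaptively in the rare case
the root lies outside), relative tolerance 10⁻¹⁵; ka ≈ ke within 10⁻¹⁰
relative is treated as the removable singularity.

### Terminal-slope extraction

The post-absorption window is every sample strictly later than the
observed peak with positive concentration, minimum three points; no
automatic lag or outlier exclusion is attempted — callers can pass
explicit indices. ke is −slope·ln 10 from an OLS fit of
log₁₀ C on t (a monoexponential has slope −ke/2.303 on a decadic log
axis). AUC is the linear trapezoid over the sampled range plus the
log-linear tail C_last/ke; this estimator exists so synthetic AUCs can
be compared against the closed form, and its error halves roughly
four-fold per halving of the sampling interval (second-order accuracy,
asserted in the tests). When a study tabulates Tmax or t½ directly,
those values take precedence over curve-derived ones, matching how the
curated dataset was originally assembled.

## Descriptors

Monoisotopic mass, Ertl TPSA and Wildman–Crippen logP are computed with
RDKit from the packaged SMILES set (13 drugs, standard PubChem neutral
structures). Two conventions are fixed deliberately:

* **Aromaticity.** The default perception treats both rings of the
  4-oxo-quinoline bicycle as aromatic (RDKit's default model). This is
  what places the ring nitrogen's TPSA contribution at its aromatic
  value and reproduces the reference table (e.g. ciprofloxacin TPSA
  74.57 Å²); the MDL perception, under which the pyridinone ring is not
  aromatic, gives a different value and is selectable
  (`convention="kekule_pyridinone"`) for sensitivity analysis.
* **Mass.** "MW" means monoisotopic mass (most-abundant-isotope sums);
  the average mass is exposed separately as `average_mass` to keep the
  two conventions from being conflated.

TPSA counts N, O, S and P environments as polar. Descriptors are
computed on the neutral species even though the energetics stage models
the cation; comparisons against the reference table are at two decimals,
round-half-even. All 13 × 3 values match at that precision.

## Chelation energetics

The modelled reaction is

    FQH⁺ + M(H₂O)₆ⁿ⁺ → [FQH·M(H₂O)₄]⁽ⁿ⁺¹⁾⁺ + 2 H₂O,   M ∈ {Mg²⁺, Ca²⁺, Al³⁺}.

The drug is modelled as the N-protonated cation (neutral 3-carboxyl,
protonated terminal amine of the R7 ring), reflecting gastric pH; the
free metal as the octahedral hexahydrate; the complex as the bidentate
chelate through the 3-carboxyl carbonyl and 4-keto oxygens with four
retained waters completing the octahedron. The displaced-water count is
a parameter (default 2) so alternative reference states can be tested.
Starting geometries place the metal equidistant from both donor oxygens
at an element-dependent distance (Al 1.9, Mg 2.1, Ca 2.4 Å) on the open
side of the pocket; non-bonded contacts below 0.7 Å are rejected. Donor
oxygens are identified by substructure (carboxyl adjacent to the ring
keto group), with a geometric closest-O-pair fallback for bare
coordinate input.

Electronic structure itself is delegated to an external engine behind an
adapter: the package emits complete, engine-agnostic staged job
descriptions — gas-phase geometry optimization and 310 K harmonic
frequencies (PBE-D3BJ/6-31G(d)), then an implicit-water (PCM) single
point (PBE-D3BJ/6-31+G(d,p)) — as canonical JSON that round-trips
byte-identically through its parser. Binding energies are assembled from
parsed energy ledgers:

    ΔE_bind = [E(complex) + 2E(H₂O) − E(FQH⁺) − E(M(H₂O)₆)] × 627.5095,
    ΔG_bind = same combination on (E_pcm_sp + G_thermal_corr,310K),

i.e. the gas-phase thermal correction is added to the solvated single
point at the optimization geometry, with no re-optimization in solvent.
Every reaction is checked for element and charge balance before any
energy is combined; 1 hartree = 627.5095 kcal/mol exactly.

The packaged ledger `fig2_energies_synthetic.json` is synthetic: its
hartree-level entries are constructed so that the displacement-reaction
bookkeeping yields the reference Gibbs binding energies (Al −16.1,
Mg −5.3, Ca +0.9 kcal/mol for ciprofloxacin). It exercises the
bookkeeping, conservation checks and ordering logic; it is not DFT
output, and tests built on it validate arithmetic and invariants, not
quantum chemistry. Running the emitted jobs through a real engine (and
hence reproducing the binding energies and the ~1.8–1.9 Å Al–O donor
distances from first principles) is deliberately outside the desk-scale
test suite.

## QSPR assembly and regression

The packaged interaction dataset has 26 coadministration arms over 13
drugs (metal, metal source, %ΔCmax, %ΔAUC, %Δka, source tag; missing
cells encoded explicitly). For the descriptor regressions one %ΔAUC per
drug is selected by source priority: aluminum hydroxide first (on ties,
the tag-71 crossover-study arm), then Maalox; drugs with neither source
are excluded and logged, leaving n = 12 (moxifloxacin has only
sucralfate and calcium arms). Regressions are simple univariate OLS with
R² = 1 − SS_res/SS_tot (equal to squared Pearson correlation, asserted);
no multivariate model is fitted.

Because the exact point membership of the published regression panels is
not printed anywhere, the assembly rule is parameterized and three
variants are documented: `default` (the literal rule above, giving
R² = 0.25 / 0.00 / 0.22 for MW / TPSA / logP), `printed-figure`
(fleroxacin taken from its sucralfate arm instead of aluminum hydroxide,
the single documented substitution under which all three panels round to
the published values 0.25 / 0.00 / 0.23), and `ciprofloxacin-72` (the
alternative aluminum hydroxide arm for ciprofloxacin, for sensitivity).
The default remains the literal rule; the one-hundredth logP discrepancy
it produces is reported as-is rather than hidden.

## Synthetic data

A scenario fixes (ka, ke, dose, F, Vd), a sampling schedule, a noise
model, and the metal-interaction effect as multipliers f_mult ∈ (0, 1]
on F and ka_mult > 0 on ka, applied to the treatment arm only. Defaults
(dose 200 mg, Vd 100 L, F = 1, ka 1 h⁻¹, ke 0.1 h⁻¹, 13 samples out to
48 h) mirror the oral FQ studies the curated dataset draws on, where
200 mg doses and multi-hour half-lives are typical. Scenario validation
requires the schedule to reach at least three half-lives past the
latest peak so a terminal phase exists in both arms.

Noise: proportional lognormal noise is median-preserving by default
(multiply by e^(σZ)); the mean-preserving convention (multiply by
e^(σZ−σ²/2)) is selectable. Additive Gaussian noise is available for
assay-floor emulation; concentrations are clipped at zero. Seeding uses
one master seed per scenario with per-(arm, subject) substreams, so
subject k's data are identical whether the cohort has 6 or 60 subjects.

Because AUC = F·D/(Vd·ke) is independent of ka in this model, the
analytic truths are %ΔAUC = 100(f_mult − 1) and %Δka =
100(ka_mult − 1); the simulator can therefore represent the clinically
observed dissociation in which AUC collapses while the apparent
absorption rate rises. What the generator does **not** emulate: gut
transit and precipitation/permeability mechanisms of chelation,
between-subject parameter variability (all subjects share the true
parameters; only noise differs), assay quantification limits, and
multi-compartment disposition. Passing recovery tests therefore
demonstrates the estimator chain is correct under the stated model, not
that the model captures every feature of real curves.

## Problem sizes and numerical checks

The test suite runs 10³ random round-trips of the peak-time inversion at
10⁻⁸ relative tolerance, 200 noisy extraction scenarios (12 samples, 5%
proportional noise; median ka error < 10%, median ke error < 3%),
simulated cohorts of 24 subjects, and 10⁴-replicate noise-moment checks;
the full suite completes in a few seconds on a laptop-class core.
Tolerances on simulated-study assertions (e.g. ±1 percentage point on a
noise-free %ΔAUC of a coarsely sampled curve) reflect trapezoid
discretization bias, not model error; tests that need the observed peak
to coincide with a sample place the true Tmax on the schedule
explicitly.

## Known limitations

* Live DFT execution, MMFF94 internals, conformer re-ranking at the DFT
  level, and 2:1/3:1 chelate stoichiometries are out of scope; the
  binding-energy regression panel therefore runs only when a user
  supplies a computed energy table with at least three drugs.
* The flip-flop ambiguity is surfaced, not resolved: for long-half-life
  drugs the reported ka is conditional on the chosen branch.
* Chelate starting geometries are idealized octahedra intended as QM
  inputs, not equilibrium structures.
* The pH-dependence of speciation (zwitterion vs cation) is fixed at the
  acidic-gut assumption.
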