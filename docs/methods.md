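# Methods

## The model

`follisim` implements deterministic mass-action kinetics for the two
signaling branches downstream of the angiopoietin receptor TEK (Tie2) in
granulosa cells of ovarian follicles:

* **Ras/ERK/MYC** — ANGPT1·TEK complexes dimerize and autophosphorylate;
  the phospho-receptor recruits Shc, Grb2 and SOS (both through Shc and by
  direct Grb2 binding); SOS complexes catalyse Ras-GDP → Ras-GTP exchange;
  Ras-GTP activates Raf1, which drives two-site distributive
  phosphorylation of MEK (→ ppMEK) and, through ppMEK, of ERK (→ ppERK);
  ppERK doubly phosphorylates MYC.
* **PI3K/AKT/mTORC1** — the phospho-receptor recruits the p85 regulatory
  subunit, which binds p110 to form active PI3K; PI3K converts PIP2 to
  PIP3 against PTEN; PIP3 recruits PDK1, which phosphorylates Akt; pAkt
  drives CREB → Mcl1 and mTORC1 → EIF4EBP1 phosphorylation.

Every step is an elementary reaction of order ≤ 2, written
`v = kf·∏[reactants] − kr·∏[products]` (a reversible step is a single
reaction with `kr > 0`, not two irreversible ones). The state derivative
is `dx/dt = N·v(x)` with `N` the species × reactions stoichiometric
matrix. Concentrations are dimensionless model units; time is seconds;
first-order constants are s⁻¹ and second-order constants (c.u.·s)⁻¹. A
saturable (Michaelis–Menten) rate form exists for single-substrate steps
but the default builder is pure mass action.

Three design features carry the biology:

1. **ANGPT2 antagonism.** ANGPT2 binds TEK competitively but its complex
   emits no phospho-receptor; raising ANGPT2 only sequesters receptor.
2. **Receptor internalization.** The phosphorylated ANGPT1–TEK dimer is
   removed first-order (`internalize_prec`), making the downstream drive
   a transient pulse. This removal also means total receptor is *not* a
   conserved moiety, unlike the strictly conserved phosphorylation
   cycles (Ras, MEK, ERK, Akt, PIP2+PIP3, CREB, Mcl1, mTORC1, EIF4EBP1).
3. **MYC turnover.** MYC is synthesised from a source and decays, with
   its phospho-forms decaying ~6× faster (phosphorylation-primed
   degradation). This is what allows total MYC to differ across
   scenarios: stronger ERK signaling routes more MYC through the
   fast-decaying phospho-pool.

## Scenarios

SF (subordinate follicle), DF (dominant follicle) and DF+miRNA share one
reaction topology. DF differs from SF only in initial amounts, by
expression multipliers: ANGPT1 ×2, TEK ×2, ANGPT2 ×0.5, Ras ×1.5, p85
×1.5 (the direction follows the reported up-regulation of ANGPT1/TEK and
down-regulation of ANGPT2 in dominant follicles; the magnitudes are free
configuration choices). DF+miRNA adds four constant (constitutively
supplied) miRNA species:

* `hsa-miR-30d-3p`, `hsa-miR-451a` → **translation block** on MYC: the
  MYC synthesis flux is divided by `1 + strength·[miRNA]`
  (noncompetitive repression; two blocks compose multiplicatively).
  Default strength 1.5 each, which lowers steady total MYC ~6-fold.
* `hsa-miR-548v`, `bta-miR-22-3p` → **receptor suppression**: a
  miRNA-catalysed first-order removal of TEK. Default rate 2×10⁻⁴
  (c.u.·s)⁻¹, deliberately weak — these miRNAs are reported
  down-regulated in dominant follicles, and the DF and DF+miRNA ppMEK /
  ppERK curves are reported to overlap; the reported direction of the
  TEK-level effect is internally inconsistent in the source material, so
  the package exposes mode and strength but asserts nothing about the
  TEK ordering itself.

miRNA pools are constant species because no turnover kinetics are
available for them; strengths are the only dose axis.

## Parameterization

The exact published rate constants live in supplementary tables that are
not redistributed here, so the default `ParameterLedger`
(provenance "literature-default") is the package's own calibration of the
under-determined kinetics. The calibration surface is the set of reported
qualitative orderings plus the printed peak times, and the defaults
reproduce them: receptor events complete within ~70 s; ppMEK peaks at
~340 s (SF) / ~275 s (DF); ppERK at ~948 s (SF) / ~652 s (DF); doubly
phosphorylated MYC at ~828 s (SF) / ~755 s (DF). The staggering arises
from phosphatase rates that fall tier by tier (MEK ~0.026 s⁻¹, ERK
~6.6×10⁻⁴ s⁻¹), so each tier integrates the one above it over a longer
window. The dominant-follicle model peaks earlier and higher everywhere
because its stronger receptor pulse saturates each tier sooner; the
subordinate model creeps up and peaks only as the drive decays — the
"SF lagging" behaviour.

Why SF ends up with *more* phospho-MYC despite *less* ppERK: total MYC
keeps accumulating (synthesis time-scale 1/0.0005 s⁻¹ ≫ window), so the
late, gentle SF conversion acts on a larger substrate pool, while the
early DF conversion burns a smaller pool and its product decays sooner.
This is the package's mechanistic reading of the reported result; it is
one consistent resolution, not the only conceivable one.

`sample_parameters` perturbs every rate constant log-normally with unit
mean factor and a given coefficient of variation; the acceptance script
reports the fraction of CV = 0.2 draws under which all orderings survive
(an output, not an assertion — with ~40 free constants, order-of-unity
robustness is not expected).

## Numerics

* Integrator: `scipy.integrate.solve_ivp`, default `LSODA`
  (stiff-capable, matching the variable-order stiff solvers conventional
  for these models); `BDF` is used as the independent second method in
  the solver-agreement test.
* Tolerances: `rel_tol 1e-8`, `abs_tol 1e-10`. Conserved totals drift
  < 10⁻¹⁴ relative over 1500 s, far inside the 100·rel_tol bound the
  package promises.
* Output grid: 1500 points over [0, 1500] s, resolving peak times to
  ~1 s; peak times are additionally refined by quadratic interpolation
  around the discrete maximum, so they are not multiples of the grid
  step. Receptor-level readouts are typically plotted on [0, 70] s.
* Negative values: the integrator is never clamped; readout evaluation
  clips at 0. Trajectories are bounded below by −10·abs_tol.
* `refine_until_converged` halves both tolerances until the probe
  readout's peak-time estimate moves less than one grid step (max 5
  refinements).
* Species whose whole trajectory stays below ~10⁻⁹ concentration units
  are compared absolutely, not relatively, in solver-agreement tests:
  below the integrator's absolute-tolerance floor a relative comparison
  is meaningless.
* Tie-break: `peak_time` returns the earliest global maximum; a maximum
  on the window edge is flagged `non_interior`; an all-zero series
  reports `t_start` with a `zero_amplitude` flag.
* "Overlap" of the DF and DF+miRNA curves is quantified as max pointwise
  gap ≤ 5% of the DF peak value.

## SBML

Models round-trip through SBML L3V1 (libsbml); L2 is accepted on read.
Kinetic laws are verified symbolically on import: anything not reducible
to the mass-action/saturable dialect raises an explicit error naming the
reaction, rather than silently mis-parsing. Parameter counts are
global + reaction-local, applied identically to in-memory models and
files. Each scenario model carries one assignment rule defining the
`ERK_active_total` observable (pERK + ppERK); the rules mechanism is
generic, and this observable is the designated substitution point if a
different algebraic rule is wanted.

## Synthetic scope and limitations

The builder is a faithful-topology reduction (~49 species, ~49
reactions) of the published ~105-species inventory, whose full species
list exists only in non-redistributed supplementary tables; exact
structural-size and peak-time reproduction against those files is wired
(import path + fidelity tests under `tests/data/supplementary/`) but can
only run where the files are present. Passing builder-mode tests show
that the implemented mechanism reproduces the reported *comparative*
kinetics under the calibrated ledger; they do not validate the published
rate constants, absolute concentration scales, or any biology outside
the modelled cascades (steroidogenesis, transcriptional feedback, ERK↔Akt
cross-talk are all absent). The model is deterministic: no cell-to-cell
variability, no stochastic (SSA) regime, no spatial structure.
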