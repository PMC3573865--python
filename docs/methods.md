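# Methods

## Copy-number quantification

A double-stranded amplicon's molecular weight is modelled as a linear
function of base-pair composition: `MW = n_AT·m_AT + n_GC·m_GC + e`, with
anhydrous average duplex pair masses `m_AT = 617.4` and `m_GC = 618.4` g/mol
and end correction `e = 0` by default. These are the standard sodium-free
average pair masses (e.g. dAMP 313.21 + dTMP 304.2 ≈ 617.4); alternative
coefficient sets — hydrated masses, 5′-end group corrections — are supported
by overriding `MassConstants`, so results computed under a different
convention can be reproduced exactly. The choice matters little in practice:
for fragments ≥ 86 bp the relative difference between coefficient sets is
well under the ~2% replicate scatter of fluorometric quantification.

Concentration is the arithmetic mean of replicate fluorometric readings
(triplicates expected). The replicate coefficient of variation is always
retained and a warning fires above 10% (configurable): pipetting scatter at
the measurement stage propagates multiplicatively into every downstream
copy number. Copies/µL = `q · 10⁻⁹ · N_A / MW` with `N_A = 6.02214076×10²³`.
Degenerate IUPAC codes are rejected in fragment sequences — an ambiguous
base has no single pair mass, and ambiguity in a cleaned, Sanger-verified
product indicates a data problem the user should resolve, not average over.

## Dilution planning and error propagation

Pipetting error is modelled as a coefficient of variation indexed by
pipetted volume, linearly interpolated between calibration nodes and never
extrapolated. The shipped default —

| volume (µL) | 1 | 5 | 10 | 100 |
|---|---|---|---|---|
| CV | 8% | 3% | 1% | 0.5% |

— is typical of air-displacement pipettes near the bottom versus middle of
their range, and is fully user-overridable. Independent step errors combine
in quadrature: `total_cv = sqrt(Σ cv_i²)`. Under this model three 1:10
steps at 10 µL aliquots carry √3·1% ≈ 1.7% total CV versus 8% for a single
1:1000 step pipetting 1 µL, which turns the familiar bench heuristic
("several small steps, not one big one") into a computable comparison.

The planner decomposes a required ratio `source/target` into the minimum
number of steps with every factor ≤ `max_step_factor` (default 10): full
`max_step_factor` steps first, one residual step last. The residual could
instead be spread evenly across steps (minimising the largest factor), but
the greedy form was chosen because it is deterministic, keeps all but one
step at the familiar 1:10, and puts the smallest transfer at the end where
the material is most dilute and least precious. Per-step CV is looked up by
aliquot volume — the small transferred volume dominates a step's relative
error; diluent-volume error is second-order and not modelled. Conservation
(`final × total_factor = source`) holds to 1e−9 relative in floating point.
Tip pre-wetting is emitted as a protocol note, not modelled numerically.

## Panel QC rules

*Melting temperature.* The Wallace rule (2 °C per A/T, 4 °C per G/C) is the
cheap default for reports; nearest-neighbour thermodynamics (Biopython's
SantaLucia unified parameters, configurable Na⁺ and primer concentrations)
is the rigorous option. Degenerate primers are expanded (cap 64 variants)
and reported as min/mean/max across expansions; the panel spread check uses
mean Tm with a default 5 °C tolerance. Reporting both methods rather than
one "true" Tm is deliberate: the two scales differ systematically and a
panel should be balanced within one scale, not across scales.

*Cross-dimers.* An ungapped antiparallel scan over all offsets finds the
longest run of complementary positions; degenerate codes pair when one
code's base set intersects the complement of the other's (N pairs with
everything). Default thresholds: run ≥ 8 anywhere, or ≥ 5 including either
primer's 3′ terminus (extensible by polymerase, the dangerous kind). A
run-length scan was preferred over duplex free energies because it is
auditable and has an exact brute-force oracle; the thresholds are
conventional screening defaults and config-exposed.

*Size spacing.* Adjacent multiplex product sizes must differ by at least the
platform's resolution: 20 bp for capillary electrophoresis, 30 bp on agarose
for fragments under 300 bp and — as a house interpolation of "increasing
with fragment size" — 10% of fragment size above 300 bp, 1 bp for dye-based
sequencers (dye channels not modelled). The bundled published panel contains
a 129/144 bp pair (15 bp gap) that the capillary rule flags; the instrument
evidently resolved it in practice, so the finding is reported as a conflict
for the designer to judge, not silently waived.

*Degraded DNA.* When targeting degraded template (gut contents, faeces,
museum material) every product must be < 300 bp (strict bound,
configurable); the check is inert otherwise.

*Amplicon prediction.* Exact degeneracy-compatible matching of the forward
primer and the reverse primer's reverse complement, products spanning both
footprints, 0-based half-open coordinates internally (1-based inclusive only
in human-readable text, labelled). Mismatch-tolerant binding is out of
scope: observed cross-reactions in the source assay traced to contamination,
not mismatch annealing, and modelling partial annealing honestly requires
thermodynamics this tool deliberately avoids.

## Balancing and limit of detection

Detection is `rfu ≥ threshold` with a closed bound at 0.1 RFU by default.
The LOD for a (target, condition) slice is the smallest tested copy level at
which **all** replicates are detected and above which no tested level shows
any failure — the "stable reaction" criterion. Grids with a failure above a
fully-detected level yield an undefined LOD with the conflict reported;
inventing a number for non-monotone data would be misleading. Levels below
the LOD with partial detection form the unstable range. Signal summaries use
the replicate median (robust to one failed lane); the mean is available.

The balancing rule mirrors bench practice: targets with summary RFU above
`median × (1 + tolerance)` lose one 0.1 µM step, targets below
`median × (1 − tolerance)` gain one, everything clamped to [0.1, 1.0] µM
(the concentration range spanned by the reference panel, including its
singleplex usage) with every clamp logged. Tolerance defaults to ±25% of the
panel median — "equal signal strength" made operational, deliberately
conservative and config-exposed. The iteration driver declares convergence
when all signals sit in the band, detects revisited concentration vectors
as oscillation (never silently loops), and bounds iterations at
`(range/step) × n_targets`.

A discreteness property worth knowing: with a proportional band and an
additive 0.1 µM step, the rule can only settle where one step moves a signal
by less than the band width — concentrations ≥ 0.4 µM for the default ±25%
band. Near the 0.1–0.2 µM floor a signal can straddle the band on both
sides of a single step and the loop correctly reports oscillation. This is
a property of the stepwise rule itself, visible at the bench as "hunting",
and the reason the toy response model used in tests starts panels at
0.4–0.8 µM.

## Synthetic data

The fixture generator emits the transcribed published panel (7 multiplex
pairs + 1 singleplex verification pair; middle-dot decimals normalised) plus
synthetic companions, all deterministic per seed:

- **Templates**: random-filler sequences flanked by the real primer
  footprints at the printed product lengths (86–228 bp, 210 bp singleplex).
  They are labelled synthetic: real amplicon sequence content (codon
  structure, GC skew, homopolymers) is not emulated, so passing tests show
  the *arithmetic and matching logic* are right, not that any biological
  inference holds.
- **Measurements**: triplicates around 10–50 ng/µL with 2% scatter, the
  working range of fluorometric quantification of cleaned PCR products.
- **Sensitivity grid**: copy levels (5, 7, 20, 30, 100, 1000) × four
  template conditions (single target; equal mix; each plus ~300 ng
  non-target background) × 3 replicates. Detected levels draw 0.3–1.5 RFU;
  at 7 copies the last replicate fails (0.02–0.08 RFU) while the others
  detect weakly (0.12–0.25); at 5 copies nothing reaches threshold. This
  encodes the reference assay's narrative — stable detection from ~20–30
  copies, unreliable replication at single digits — because the underlying
  per-replicate table was never published; the grid supports logic tests,
  not sensitivity claims about any real assay.
- **Toy response model** for balancing tests: linear `rfu = efficiency ×
  concentration` with per-target efficiencies uniform in [0.7, 1.4] (the
  magnitude of spread an unbalanced panel shows) and starting
  concentrations on the 0.1 µM grid in [0.4, 0.8] µM, the regime where the
  stepwise rule is contraction-like (see above). Real PCR response is
  saturating and noisy; the linear model tests the loop, not the chemistry.

## Numerical choices

- All mass/copy arithmetic in double precision; stated test tolerances are
  relative (1e−9 for conservation and round-trips, 1e−14 where the identity
  is exact up to float summation order).
- Dilution factors may be non-integral; volumes follow from
  `aliquot × (factor − 1)`.
- Degeneracy expansion is capped (default 64) and over-cap primers are an
  explicit error rather than a silent subsample.
- Ties in plan comparison (CV difference < 1e−12 absolute) report as
  equivalent.

## Limitations

- No PCR kinetics: the toolkit evaluates and proposes; it never simulates
  amplification, so balancing against real data requires a bench re-measure
  per iteration.
- No thermodynamic duplex energies, secondary structure, or
  mismatch-tolerant binding prediction.
- No correction for residual genomic DNA co-measured with the cleaned
  product (a small overestimate of copies, negligible against PCR yield).
- The quadrature error model assumes independent, volume-indexed pipetting
  errors; systematic miscalibration is not representable.
- Monte-Carlo simulation of realised concentrations, liquid-handler
  programming and consumable tracking are out of scope.
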