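# Methods

## Motif model and scanner

A standard k-turn is modelled as: a bulge of exactly three nucleotides on
one strand of an antiparallel duplex, flanked 5′ by the canonical (C)
helix and 3′ by the non-canonical (NC) helix whose first two pairs are the
sheared 1b:1n = G:A and 2b:2n = A:G. Sequence coordinates are 0-based
half-open; the signed k-turn labels (−1b, 3n, L1 …) are a separate
coordinate system mapped explicitly, so annotations carry both.

The scanner enumerates every bulged register of the two strands in both
polarities (the bulge may sit on either input strand; a self-hybridizing
strand is scanned as the same sequence twice). A register is reported when

* the sheared signature holds at indices 1 and 2;
* at least `min_c_pairs` (default 3) C-helix pairs are Watson–Crick or G:U
  wobble;
* at least `min_nc_pairs` (default 4) NC-helix pairs exist, with index 3
  unconstrained (all 16 base combinations occur in natural k-turns) and
  indices ≥ 4 WC/wobble.

The defaults mirror the canonical experimental construct (three C-helix
pairs, the loop, four NC-helix pairs); both are configurable because
natural k-turns vary. Helices are extended maximally outward; overlapping
registers are all reported (no greedy suppression) and downstream
consumers filter. Limitations: 2- or 4-nt bulges are not standard k-turns
and are never reported; k-junctions (three-way junctions) are out of
scope. The dot-bracket front end supports plain `()` structures only;
pseudoknot brackets are rejected with a parse error. A 3×0 internal loop
is the secondary-structure equivalent of the bulge, and both strand
orientations of a stem are examined through the pairing map.

## Folding and conformation rules

The rule engine is deliberately a transparent decision list, evaluated in
a fixed order with every step recorded in the trace (stable, versioned
rule ids such as `R1-3bn-WC`):

1. −1b:−1n = G:C → DOES_NOT_FOLD (terminal);
2. Watson–Crick 3b:3n → DOES_NOT_FOLD (rule 1, overriding rules 2–3; G:U
   counts as wobble, not WC);
3. 3b = C or 3n = G → FOLDS; any other 3b:3n → INDETERMINATE;
4. −1b:−1n modifier: A:U keeps the class, lowers the apparent-affinity
   hint (K_d 106 vs 70 μM in the characterized background); U:A
   downgrades FOLDS → FOLDS_WEAKLY;
5. 4b:4n = G:U raises the affinity hint; in a weak background it is
   recorded as a partial rescue *without* upgrading the class, because the
   characterized U:A + G:U construct remains clearly weaker than the
   well-folding k-turns. This conservative reading keeps class and
   affinity as separate axes.

Combinations outside the characterized set return INDETERMINATE (folding)
or UNKNOWN (conformation) rather than guessing: the full 16-cell grids
exist in the literature but are shipped only as an extension point (a TSV
override table), not as built-ins. U:A over an already-INDETERMINATE base
class is marked low-confidence in the trace.

## FRET analysis

`model_efret` implements the two-state isotherm exactly; the folded
fraction follows single-site binding, so E_FRET rises hyperbolically in
[Mg²⁺] from E₀ to E₀ + ΔE_FRET with midpoint at the apparent K_d = 1/K_A.
Concentrations are molar internally; the CLI converts declared μM/mM.

Spectral preprocessing: a doubly-labelled emission spectrum is decomposed
by linear least squares onto donor-only/acceptor-only reference spectra
(interpolated to the common grid; collinear references are rejected by an
SVD condition test). The acceptor-normalization identity converts the
acceptor amplitude under donor excitation, the directly excited acceptor
emission, and the three extinction ratios into E_FRET; being a ratio of
two signals from the same sample it is concentration- and
scale-invariant. The identity is documented in the function docstring;
precomputed E_FRET tables can bypass the spectral path entirely.

Fitting: unweighted nonlinear least squares (Levenberg–Marquardt via
lmfit), per-point σ weighting optional. Initialization is data-driven
(E₀ = min E_FRET, ΔE = range, K_A = reciprocal concentration at half-rise
by linear interpolation) and augmented by a 7-point log-spaced K_A
multi-start spanning the measured concentration window, keeping the
lowest-RSS optimum — the isotherm develops shallow side minima when ΔE is
comparable to the noise. Standard errors come from the local quadratic
approximation; non-convergence and non-identifiability (flat titrations,
K_A stderr > 10× estimate) are flagged on the result, not raised. A
case-resampling bootstrap (seeded) provides percentile intervals for K_d,
since point estimates alone understate its sampling variability.

### Synthetic titrations and what they show

`simulate_titration` draws i.i.d. Gaussian noise around the exact isotherm
at chosen concentrations, reproducible under a seed. The recovery studies
use the published operating points of the characterized constructs
(E₀ = 0.25 for the shared 25-bp duplex background; plateaus 0.56 / 0.30 /
0.67 / 0.60 and K_d 70 / 231 / 44 / 8 μM for wild type, U:A, G:U and drum
respectively), 20 log-spaced points from 1 μM to 10 mM (0.5 μM for drum,
whose K_d of 8 μM needs the lower decade), σ = 0.02, 100 replicates. These
sizes run in seconds on one CPU.

The generator emulates the *statistical* structure of an acceptor-ratio
titration (homoscedastic Gaussian point noise around a two-state curve).
It does not emulate pipetting-correlated errors, baseline drift,
photobleaching, deviations from two-state behaviour (e.g. sequential ion
binding), or replicate-to-replicate E₀ variation — so parameter-recovery
results certify the estimator under the stated noise model, not the full
experimental error budget.

A known property of the estimator, visible in these studies: when ΔE_FRET
is only a few times the point noise (the U:A construct: ΔE = 0.05 vs
σ = 0.02), the per-replicate K_d distribution is broad and right-skewed
and its median sits 10–20% below truth at σ = 0.02, converging to truth as
σ → 0 (asserted by the test suite). This is intrinsic to maximum-likelihood
K_d estimation at that signal-to-noise, not an optimizer artifact — an
independent `scipy.optimize.curve_fit` route reproduces it.

## Structural classification

Crystal structures at the relevant resolutions lack hydrogens, so all
hydrogen-bond criteria use heavy-atom donor–acceptor distances with a
3.5 Å default cutoff (configurable). Decision logic of `classify_N3_N1`:

* primary: the smaller of d(−1n O2′⋯A2b N3) and d(−1n O2′⋯A2b N1)
  decides, provided it is within the cutoff;
* secondary consistency: d(A2b N6⋯G2n N3) ≤ 3.5 Å supports N3; ≥ 4.5 Å
  supports N1 (threshold set below the observed ≈ 5.3 Å lengthening with
  margin); intermediate values abstain;
* disagreement, or missing required atoms, yields UNKNOWN with the
  measured distances and the reason — never an exception;
* the report additionally verifies the conserved cross-strand bond
  L1 O2′⋯A1n N1 and the sheared geometry of both tandem G:A pairs
  (G N2⋯A N7 required; A N6⋯G N3 reported only, since it lengthens in
  N1), and the G:U wobble test requires both G O6⋯U N3 and G N1⋯U O2.

Residue mapping is user-supplied (TSV: label, chain, resnum); where a
structure contains several copies of the motif, each mapped copy is
classified independently.

Helix axes are estimated as the principal direction of base-pair
midpoints (C1′ atoms, P fallback), oriented along the 5′→3′ pair
ordering. This is approximate (~±5°) but sufficient to separate the
tightly kinked k-turn regime (≤ 70° flagged "kinked") from coaxial
geometry; full helicoidal parameter fitting is deliberately out of scope.

### Synthetic geometries

`make_synthetic_kturn_core` builds an idealized hydrogen-bonding core from
standard-frame adenine geometry: the sheared G2n contacts, the −1n O2′
placed 2.8 Å from the chosen acceptor (N3 or N1) on the line through the
rival acceptor (so the rival distance is always ≥ ~5 Å), the A2b N6⋯G2n
N3 contact at 2.8 Å (N3) or 5.3 Å (N1), and the L1 O2′⋯A1n N1 bond; the
assembly receives per-atom Gaussian jitter (0.05 Å) and a seeded random
rigid motion. These are validation fixtures for the classifier's decision
logic — labelled synthetic throughout — not models of any deposited
structure; classifying real crystal structures requires the corresponding
coordinate files and a residue map. Similarly the synthetic duplex
generator places paired C1′ atoms diametrically on a cylinder so that
base-pair midpoints lie exactly on the intended axis, giving
ground-truth-exact axis tests.

## Numerical and design choices

* 0-based half-open sequence spans everywhere; nomenclature labels mapped
  explicitly (prevents off-by-one drift between coordinate systems).
* T is accepted and normalized to U with a one-time warning so
  DNA-alphabet FASTA files work; any other non-ACGUN symbol is an error.
* G:U is never Watson–Crick in this package: it is the wobble class with
  its own structural role.
* Ties in the primary conformation criterion (d_N3 == d_N1 within float
  equality) resolve to N3; in practice the two distances differ by > 1 Å
  in all tested geometries.
* Fit determinism: identical input and initialization give identical
  results; all simulation seeds are explicit and recorded in reports.
* Annotation JSON uses stable documented field names (`c_pairs`, `loop`,
  `nc_pairs`, `b_strand_span`, `n_strand_span`, `source_ids`).

## Known limitations

* Only standard 3-nt-bulge k-turns are detected; k-junctions and
  non-standard bulge sizes are not.
* Folding prediction is qualitative (class + affinity hint); the package
  does not predict numeric K_d from sequence, loop-sequence effects, or
  protein (L7Ae)-induced folding, which occurs for most k-turns regardless
  of ion-folding class and therefore carries no discriminative signal.
* The built-in conformation table covers only the pairs characterized
  here; the override TSV is the supported way to complete the grid.
* The two-state isotherm assumes a single apparent ion-binding event; no
  Hill coefficients or multi-site models.
* Instrument corrections (lamp fluctuation, polarization) are assumed
  applied upstream of the spectra handed to this package.
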