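# Methods

## Model

The observable is the isotope envelope of an intact peptide carrying one
slowly exchanging site, the histidine imidazole C2 (Cε1) proton. The
envelope at any time is modeled as the two-component mixture

    env(t) = (1 − d(t)) · natural + d(t) · shift(natural, +1)

where `natural` is the peptide's natural isotopic distribution and
`shift(·, +1)` moves every peak one integer offset up. The single-site
occupancy follows pseudo-first-order kinetics:

* uptake (HDX, incubation in D2O): `d(t) = 1 − exp(−k t)`;
* loss (DHX, deuterated peptide in H2O): `d(t) = d0 · exp(−k t)`.

Two estimators of `d` are implemented. The two-peak statistic
`Y = I_{M+1}(t)/I_M(t) − I_{M+1}(0)/I_M(0) + 1` equals `1/(1 − d)` exactly
under the mixture model and uses only the M and M+1 peaks; it drives the
HDX fit (`ln Y = k t`, least squares through the origin — the reference
envelope *defines* t = 0, so the regression has no intercept). The
mixture-deconvolution estimator projects the observed envelope onto the
segment between `natural` and its +1 shift using all peaks (a closed-form
constrained least square); it drives the DHX fit
(`ln d = ln d0 − k t`, free intercept), where the M peak of a
highly deuterated start is too small for a stable two-peak ratio. Both
fits are unweighted in log space. Points whose statistic is non-positive
under noise are excluded with a warning rather than clamped, because
clamping biases the log-space slope; points flagged as post-quench holds
(exchange stopped by acidification) are likewise excluded, which makes the
fitted k exactly invariant to appending such holds.

The pH dependence of k is the titration sigmoid
`k(pH) = k_max / (1 + 10^(pKa − pH))`: exchange requires the protonated
(imidazolium) ring attacked by deuteroxide, so the rate rises with pH to
the plateau `k_max`, with the ring N–H pKa at the inflection. The fit runs
in the k-domain by nonlinear least squares (parameter tolerance 1e-10),
not in the linearized pointwise form `pKa = pH + log10((k_max − k)/k)` —
the linearization amplifies noise without bound as k approaches k_max, and
cannot use points whose noisy rate estimate is 0 or ≥ k_max. The pointwise
form is retained as a diagnostic. Initialization: k_max at 1.05× the
largest observed rate, pKa at the pH whose rate is nearest half of that;
this lands inside the attraction basin for any profile that actually spans
its inflection. Zero-rate observations are accepted as data; an all-zero
profile is an error. Unweighted by default (a weighted option scales
residuals by per-point rate standard errors when present), since nothing
in the model prescribes a weighting.

Phosphorylation of a ring nitrogen places a negative charge next to C2 and
suppresses k by roughly two orders of magnitude. The call compares an
observed rate against an unmodified reference on a log scale:
`ratio_orders = log10(k_ref/k_obs)`, called phosphorylated at ≥ 1.5
orders, indeterminate within 0.25 orders below that, unmodified otherwise.
The threshold sits about one order below the empirically observed ~1.9-order
separation of the reference panels, so a noisy rate fit does not flip the
call; the indeterminate band acknowledges that a hard boundary on a noisy
log-ratio is a coin flip. A zero observed rate saturates to a
phosphorylated call. Panel spreads use the *population* SD (divisor n):
with seven-peptide panels this is the convention that reproduces the
printed relative spreads (8.4 %, 15.1 %) of the shipped reference tables.

## Parameters and units

| parameter | default | meaning |
|---|---|---|
| k | — (fit) / 0.027 h⁻¹ (sim) | pseudo-first-order exchange rate; time unit is hours throughout |
| d0 | 0.95 | initial deuterated fraction of a loss series (preparation leaves a few percent unlabeled) |
| pKa, k_max | — (fit) | titration parameters; pH and pD readings are treated as one axis with no glass-electrode correction (an optional fixed offset can be applied upstream) |
| noise_sigma | 0.03 | multiplicative Gaussian SD per peak intensity |
| phospho_suppression | 0.013 | rate multiplier for a phosphohistidine peptide (the ~1.9-order observed suppression) |
| residual_labile_fraction | 0 | workup artifact: fraction of molecules retaining one labile deuteron after back-exchange |
| occupancy_threshold | 0.05 | minimum mixture weight for a shift to count as an exchanged site |
| threshold_orders | 1.5 | phosphorylation call threshold, with a 0.25-order indeterminate band |
| ppm_tol | 10 | centroid-to-lattice matching tolerance for m/z peak lists |

Isotope envelopes are computed by exact per-element polynomial convolution
(truncated at the requested number of peaks, then renormalized), using the
pyteomics NIST/CIAAW isotope table; no averagine approximation — the
target peptides are ≤ 9 residues, so exactness is cheap and lets every
envelope be checked against a brute-force convolution oracle. Envelopes
live on an integer-offset lattice: the ~2.9 mDa difference between a 2H
substitution and a 13C peak is deliberately not resolved, matching the
unit-resolution two-peak statistic. β-linked Asp is treated as
compositionally identical to Asp (mass-identical isomer), and the
phospho-His composition delta is fixed at HPO3 with no τ/π isomer
distinction — the implemented observables cannot tell the isomers apart.
For multi-His peptides the exchange site is a user designation, never
inferred: intact-peptide envelopes cannot localize the site (that requires
the b/y fragment workflow, whose His-containment flags this package
computes).

## Synthetic data

The generator emulates: single-site exponential uptake/loss on the natural
envelope, per-peak multiplicative Gaussian noise (σ default 3 %, a
modeling choice that gives scatter comparable to real rate-vs-pH panels —
no noise model is prescribed by the underlying chemistry), an optional
residual-labile-deuterium contamination shifting a fraction of the pattern
one further offset, phosphorylation as a pure rate suppression of the same
law, and acid-quench holds. It does **not** emulate chromatography,
ionization efficiency, charge-state distributions, isotope fine structure,
overlapping species, or amide-backbone exchange; passing tests therefore
demonstrate correctness of the estimators under the stated mixture model,
not robustness to every instrumental artifact of real spectra. Noise draws
that go negative are truncated at zero and counted in the series metadata.
Randomness is reproducible: one master seed, per-series substreams derived
by stable hashing of (sequence, pH, direction), so fixture sets are
byte-identical regardless of generation order. Default grids: uptake
{0, 6, 12, 24, 48} h (~2 half-lives at the unmodified plateau rate), loss
{0, 8, 24, 48, 96} h, pH {6.0, 6.8, 7.3, 7.8, 8.6, 9.2} (spans the
imidazole pKa region of short model peptides plus plateau coverage). These
grids are package conventions; the experiments the reference tables came
from did not publish theirs.

## Numerical choices and degenerate inputs

* The deconvolution estimate of d is a scalar projection clipped to [0, 1];
  d = 1 is reported with a saturation flag instead of an infinite Y.
* Site counting solves a non-negative least-squares mixture over shifts
  0..max_sites and reports the largest shift at or above the occupancy
  threshold — the automated form of the "exactly one deuteron
  incorporated" check run before a loss experiment.
* The DHX fitter reconstructs the theoretical natural envelope with one
  peak fewer than the observed envelopes, because an observed envelope
  spans the natural lattice plus the +1 exchange offset; mismatching the
  two lattices introduces a ~1e-8 relative rate bias, which matters at the
  package's own 1e-9 exactness tests.
* Profile fits attach warnings instead of silently answering on degenerate
  coverage: all rates within 60 % of each other (titration region not
  sampled — e.g. a pH grid entirely above pKa + 2), largest observed rate
  well below the fitted plateau, or a fitted pKa outside the scanned range
  ± 2 units.
* Rate constants are clamped at 0 when a noisy slope comes out with the
  wrong sign; half-life of a zero rate is reported as +inf.

## Reference tables

The shipped `table1.tsv` (seven unmodified peptides: pKa and plateau rate
for both exchange directions) and `table2.tsv` (the same panel
phosphorylated: rates at pH 7.9/8.2/8.7/9.0) store rate columns in the
printed unit of 1e-4 h⁻¹. Two transcription caveats are documented rather
than silently resolved: the source's column labels for the two direction
panels appear swapped relative to its surrounding prose (the range and SD
quoted in the uptake discussion match the loss-labeled column — summaries
here reference columns by their printed labels); and the source's prose
gives the phosphopeptide rates as ~2.4–5.4 × 10^4 h⁻¹ while its table
header says ×10^−4 h⁻¹ — the table header is followed, as only it is
consistent with a near-flat loss series over 96 h.

## Limitations

Per-peptide pKa/k_max values of the reference panel cannot be re-derived
from shipped data (the underlying rate-vs-pH measurements are not
published); they are exercised instead as round-trip identities — noiseless
recovery to ≤ 1e-6 relative error and seeded noisy recovery (3 % intensity
noise, 200 replicates per peptide and direction) with median pKa error
≤ 0.1 units and median relative k_max error ≤ 5 %. The package fits
single-exponential kinetics only (no multi-exponential or stretched forms,
no EX1/EX2 analysis), handles singly charged fragment b/y ions only, and
reads centroided peak lists (profile-mode and vendor raw data are out of
scope; mzML ingestion is a possible extension, required by nothing here).
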