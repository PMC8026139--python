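# Methods

This note records the models implemented in `anthochrome`, the defaults
and why they were chosen, what the synthetic fixtures do and do not
emulate, and the numerical conventions that affect results.

## Spectral metrics

A `Spectrum` is a strictly increasing wavelength grid with absorbance in
AU; at least two points, finite values, no duplicate wavelengths.
Absorbance is deliberately *not* clipped at zero — baseline noise can dip
negative, and clipping would bias area statistics upward.

**λmax** is the global maximum of the sampled absorbance restricted to an
analysis window (default 400–700 nm, the visible band). Ties on a
plateau break toward the longer wavelength so the output is
deterministic; this matters only for flat-topped or saturated bands.

**Violet contribution (VC)** is the left Riemann sum of absorbance over
[500, 600) nm: rectangle height = absorbance at the left endpoint,
width = the spectral resolution. The 600-nm sample itself contributes no
rectangle. The definition presumes a uniform grid, so non-uniform
spectra are first resampled (linear interpolation) to a 1-nm grid. A
left sum on a smooth band differs from true quadrature at first order in
the grid spacing; the test suite pins VC against a 0.1-nm trapezoid
oracle to within 1% and checks monotone convergence under grid
refinement. VC is linear in absorbance and is reported in nm·AU.

**Bathochromic shift** is λmax(shifted) − λmax(reference); positive
values are red-shifts. On 1-nm fixture grids the metric is exact to the
grid.

## Colorimetry

The chain is transmission colorimetry of a solution: T(λ) =
10^(−A(λ)·path_scale) clipped to [0, 1]; X, Y, Z = k·Σ T·S·(x̄, ȳ, z̄)·Δλ
with k normalising Y = 100 for a perfect transmitter; CIELAB with the
standard (6/29)³ linear segment; hue h = atan2(b*, a*) in [0, 360);
ΔE\*ab as the CIE76 Euclidean distance. On the neutral axis
(a* = b* = 0) the hue is undefined and returned as `None` rather than an
arbitrary angle.

Observer and illuminant are explicit configuration, defaulting to the
CIE 1931 2° observer under D65 — the conventional choice for
transmission work when no instrument geometry is specified. The 5-nm
CMF and D65 tables ship in `anthochrome/data/` (standard published
tables, transcribed at 5-nm resolution) and are interpolated linearly to
the configured step (default 1 nm). The D65 whitepoint computed from
these tables reproduces the standard (95.047, 100, 108.883) to better
than 0.05%, which bounds the table-transcription error. Verification is
dual-route: the CIELAB formulas are checked against scikit-image to
1e-6 with a shared whitepoint, and the spectral integration against an
independently coded second implementation of the same tables. Hue-angle
matching between colorants is reported as |Δh| in degrees together with
ΔE\*ab, because replacement arguments for colorants are hue-led.

Limitations: this predicts solution transmission color only. Reflectance
colorimetry of coated products (pan-coated lentils and the like), CIEDE2000,
and gamut mapping are out of scope.

## Flavylium multistate and pK′h fitting

The multistate is lumped to three pools: flavylium cation AH⁺ (reference
concentration 1), quinoidal bases at 10^(pH−pKa), and colorless
hydration products (hemiketal + chalcones) at 10^(pH−pK′h). The colored
fraction is

    f(pH) = (1 + 10^(pH−pKa)) / (1 + 10^(pH−pKa) + 10^(pH−pK′h))

monotone non-increasing in pH and bounded in [0, 1]. The internal split
of the colorless pool cancels, which the tests exploit as a brute-force
species-balance oracle.

**pK′h fitting** uses the restricted two-parameter sigmoid A(pH) =
A₀/(1 + 10^(pH−pK′h)), valid in the acidic regime where quinoidal bases
are negligible (below ~pH 6) — the conventional way an *apparent*
hydration constant is measured from equilibrium-endpoint absorbances.
The fit is nonlinear least squares (lmfit/Levenberg–Marquardt) with
deterministic data-driven starts: A₀ at the maximum absorbance, pK′h at
the interpolated half-maximum crossing. Standard errors come from the
covariance at the optimum; a series that does not span the transition
(min > 25% or max < 75% of A₀) is flagged rather than rejected. The
endpoint assumption (as opposed to pH-jump initial rates) is a modelling
choice of this package and is what the titration generator produces.

Default titration conditions: 26 points over pH 0.5–6.5, noise 0.005 AU,
A₀ = 1. Under these conditions the fitter recovers a truth of 4.4 to
±0.01 typically; the suite requires ±0.05 for a single series and a
median absolute error < 0.03 with 95% CI coverage in [90%, 99%] over 200
replicates.

## Degradation kinetics

Fading is fitted mono-exponentially, A(t) = A₀e^(−kt), k ≥ 0 enforced by
bounds, initialised from a log-linear regression (exact on noiseless
data). Half-life = ln 2/k, with an infinite sentinel at k = 0. Percent
loss at time t is 100·(1 − e^(−kt)) from the fitted model; extrapolation
beyond the observed span warns. A biexponential model was considered and
rejected as default: the reported stability figures are single percent
losses, which a one-rate model reproduces exactly, and a second rate is
unidentifiable from the small fixtures. Autoxidation is not modelled
separately; k lumps all first-order loss channels.

## Exact mass and stoichiometry

Formulas are element-count records with a signed charge and exact
add/subtract/scale algebra (negative counts are errors). Monoisotopic
masses use a bundled table of most-abundant-isotope masses
(CODATA/IUPAC values, cross-checked against pyteomics in the tests) and
subtract one electron mass per positive charge (add per negative): at
10-ppm tolerance near m/z 1000 the electron mass (~0.5 ppm per charge)
is not negligible. Average-mass mode is deliberately absent — the target
data are TOF measurements.

Anthocyanin composition: cyanidin flavylium core C₁₅H₁₁O₆⁺, plus
C₆H₁₀O₅ per glucosyl, C₉H₆O₂ per p-coumaroyl, C₁₀H₈O₃ per feruloyl,
C₁₁H₁₀O₄ per sinapoyl — each residue already condensed (one water
removed per bond). P2 composes to C₄₄H₅₁O₂₅⁺ (979.2714 Da as the
cation).

Complex ions are [k·L + metal − n·H]^z. Bracket notations in the
literature are ambiguous about whether "L" counts the flavylium cation
or a neutral base, so the hydrogen-loss count n is a free search
variable and matching is done purely on mass; the implied n is reported.
The assignment search enumerates k = 1–6, n = 0–12, z = ±1–±4 (charge
sign affects only the electron term and is usually indistinguishable),
scores each candidate in ppm, and reports matches within tolerance
(default 10 ppm, the externally calibrated ESI-TOF regime) ranked by
|ppm|. The consensus ligand count is the unique k that matches every
observed peak. For the P2/Al system the two observed multivalent peaks
are matched only by k = 3 (at n = 7 and n = 8, consistent with three
flavylium cations each losing their phenolic protons on complexation
plus the charge-carrying deprotonations).

Isotope-envelope simulation and raw-spectrum parsing are out of scope.

## Chromatography

Peak detection runs `scipy.signal.find_peaks` with thresholds derived
deterministically from the data: height 5× and prominence 2× a robust
noise SD (median absolute successive difference / (0.6745·√2), which is
stable on baseline-dominated traces and zero on noiseless fixtures).
Peak boundaries sit at the signal minima between adjacent apexes
(valley-to-valley); integration is trapezoid area above a *linear*
valley-to-valley baseline per peak, negative net areas clamped to zero
with a warning. Overlapping peaks split at the valley (perpendicular
drop); no deconvolution. These are routine DAD-workflow conventions,
adequate for well-separated synthetic peaks; heavily fused peaks would
need deconvolution this package does not attempt.

Assignment maps detected apexes to a reference time table (packaged
P1–P8 times) by nearest-within-tolerance, nearer peak winning conflicts;
assignment never alters areas. Conversion metrics compare *relative*
areas between runs (robust to injection volume): converted fraction of a
peak group = 1 − Σafter/Σbefore, with `complete` flagged at ≥ 0.99 for
P3–P8 jointly, and a `None` sentinel when the group had no area before.

## Sequence screen statistics

Percent identity = 100 × identical columns / full alignment length
*including gap columns*, from a pairwise global Needleman–Wunsch
alignment (Biopython `PairwiseAligner`): BLOSUM62 with gap open −10 /
extend −1 decides the alignment path; identity is then counted on that
path. The gaps-in-denominator convention is what produces the very low
identities (single digits to low tens of percent) quoted for screens
spanning unrelated families. Of multiple co-optimal alignments the
aligner's first is used; the tests verify optimality and identity
against exhaustive enumeration of all alignments on short sequences.

Pairwise identity from an MSA (as GUI tools compute it) is a different
statistic and is deliberately not implemented: it depends on the whole
sequence set and the MSA heuristic, and is not reproducible from pairs.
Consequently the absolute medians of a screened panel under this
package's convention differ from MSA-derived values; what carries over
is the *ordering* — an active subset forming a family is more
self-similar than the panel at large — and that ordering is what the
fixtures and tests pin down. Measurement during development showed that
under this alignment scheme even unrelated equal-length random proteins
score a median ≈ 16% identity (cheap gap extension pairs identical
residues), so single-digit medians arise only from length-mismatched
pairs; this is documented here so nobody tunes the generator chasing
absolute median targets that the convention cannot produce. A
tree is out of scope; `write_phylip_distances` exports 100 − identity
for external tree builders.

## Synthetic fixture library

The generators produce every input the pipeline consumes; their defaults
*are* the study conditions, and each output carries a provenance note
naming the reported value it is calibrated to.

- **Spectra**: sums of Gaussians on a 400–700 nm, 1-nm grid (extendable
  to 380–780 nm for colorimetry). Only band *centers* are calibrated
  (to the reported λmax values: 630/617/608/640 nm for the four blues;
  598→640, 596→602, 598→617 nm for P2/P5/P8 ± Al); widths (σ = 35 nm
  main, 45 nm shoulder) and shoulder heights are artifact choices. Where
  a violet-side shoulder would pull the apex of the band sum off the
  main center (crude extract, spirulina), the main center is nudged
  iteratively until the continuous apex sits exactly on the calibrated
  λmax, so the grid argmax reads the integer target. Shoulders are
  placed so the violet-contribution ordering (complex < synthetic cyan <
  crude extract) holds.
- **Decays**: A(t) = A₀e^(−kt) with rates pinned analytically to the
  reported calibration points — k = −ln(0.43)/10 per day for the crude
  syrup (57% loss at day 10) and k = −ln(0.86)/55 for the complex (14%
  at day 55) — so the fit → percent-loss round trip is exact on
  noiseless data. Aqueous-series rates reproduce only the qualitative
  stability ordering and are marked as artifact choices. Sampling grids
  (daily over 10 days; weekly over 56) are artifact choices, since no
  sampling intervals are reported.
- **Titrations**: generated from the restricted hydration sigmoid
  (deprotonation disabled) with truths at the reported pK′h values
  (P1 2.1, P5 2.7, P8 3.7, P2 4.4), 26 points over pH 0.5–6.5, noise
  0.005 AU.
- **Chromatograms**: eight Gaussians (σ = 0.15 min) at packaged
  reference times on a 0–30 min, 0.01-min grid. Untreated relative
  areas (6, 4, 10, 12, 16, 14, 18, 20%) are artifact choices satisfying
  the reported <5% natural abundance of P2; the complete-conversion
  treatment moves P3–P5 into P1 and P6–P8 into P2 leaving 0.05% residue
  per acylated peak; the partial treatment halves P6–P8 into P2.
- **Protein panels**: 46 sequences, 17 active. Actives descend from one
  ancestor (per-site substitution rate 0.55, terminal trims/extensions
  to 220–380 aa); inactives are unrelated random sequences with natural
  amino-acid composition, 100–550 aa.

All stochastic generators consume one explicit seed per call through
`numpy.random.default_rng`; no global state, and identical seeds give
bit-identical outputs.

What the fixtures do **not** emulate: real band asymmetry and solvent
effects in spectra, correlated (non-white) detector noise, chromatogram
baseline drift and tailing, pH-jump kinetics in titrations, biphasic
degradation, and real esterase phylogenetics. Passing tests therefore
demonstrate correctness of the *computations* under controlled
conditions, not robustness to every artefact of instrument data.

## Pipeline and reproducibility

`run_pipeline` executes the configured stages on the fixture library and
writes one JSON report per stage plus a combined summary; all numeric
outputs carry units, timestamps are confined to logs, and identical
config + seed reproduces reports byte for byte. Configuration is a
single YAML-able record validated with unknown-key rejection; CLI flags
override file values. `scripts/acceptance.py --seed N --out f.json`
recomputes the two headline quantities (bathochromic shift; untreated P2
relative area) from scratch at problem sizes of 301 spectrum points and
3001 chromatogram samples — small enough to run in seconds while leaving
the quantities grid-exact.
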