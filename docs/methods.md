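# Methods

## The phasor representation and the Δω observable

A TCSPC decay histogram over one laser period T is summarised by its
first-harmonic Fourier coefficients g = Σc·cos(ωt)/Σc, s = Σc·sin(ωt)/Σc
with ω = 2π/T, evaluated at bin centers. Single-exponential decays of
lifetime τ sit on the universal circle at g = 1/(1+(ωτ)²),
s = ωτ/(1+(ωτ)²); mixtures sit at the intensity-weighted mean of their
component phasors (linearity is exact for the discrete transform, and the
suite asserts it as a property). Because the histogram is truncated at
exactly one period and the harmonic frequency satisfies e^{iωT} = 1, the
truncated single-exponential phasor equals the analytic one up to
discretisation error of order (ωΔt)²/24 — negligible at the default 256
bins.

The FRET observable is the phase-angle displacement

    Δω = atan(ω·Tau1) − atan2(s, g)     [radians]

of a calibrated sample phasor from the donor-only reference lifetime
Tau1. It is zero for unquenched donors, positive when FRET shortens the
donor lifetime, strictly decreasing in the sample lifetime, and bounded
by atan(ω·Tau1) (the zero-lifetime limit). We use radians throughout;
the magnitudes involved (0–0.2 for full binding curves, 0.05 as the
dynamic-range threshold) are consistent with that reading of the
"angular change" convention, and output metadata states the unit.

Calibration is single-point: the measured phasor of a reference
fluorophore well is rotated/rescaled onto its analytic position. The
reference lifetime defaults to 4.0 ns (the conventional fluorescein
value; configurable). A quenched-fluorescein (near-zero-lifetime) well
can be used to sanity-check the rotation but is not a second constraint.
Donor-only wells define Tau1 as the mean phase lifetime across those
wells.

The 350-ps early window estimates donor brightness independently of
FRET: quenching redistributes photons across the period but barely
changes the count arriving in the first ~0.1 τ, and the suite's test
demonstrates the suppression on equal-amplitude decays.

## The binding model and the generator

A 1:1 equilibrium with dissociation constant Kd gives the bound complex

    B = 2DA / (S + sqrt(S² − 4DA)),   S = D + A + Kd

(the numerically stable root of the binding quadratic). An exact
consequence is that the donor bound fraction is a Hill function (h = 1)
of the *free* acceptor: f = A_free/(Kd + A_free), for any donor
concentration. The generator exploits this: binding-mode ROIs draw donor
~ U(1, 3) µM and acceptor over 0–50 µM, compute f exactly, and set the
noiseless readout to Δω_max·f, where Δω_max is the phase shift of a
donor whose lifetime drops from τ_D to τ_D(1−E). The analysis path
therefore recovers the generating Kd without model mismatch, which is
the point: the acceptance harness tests the inference chain, not a
discretisation accident. Collision mode sets Δω = 0.003 rad/µM × acceptor
(linear, unbounded); mixed mode superimposes both.

Acceptor concentrations are log-uniform by default (floored at 0.05 µM
when the range starts at 0) because high-intensity ROIs are rare in real
screens: this populates the low bins with thousands of ROIs and the
40–50 µM bin with ~100 at the default 3000 ROIs/replicate, matching the
reported structure of such screens. Uniform sampling is a flag away.

Defaults, with rationale:

| parameter | default | why |
|---|---|---|
| τ_donor | 3.8 ns | typical bright cyan FP lifetime; configurable |
| laser period | 12.5 ns | 80 MHz Ti:Sapphire convention |
| time bins | 256 | standard TCSPC resolution per period |
| noise sd on Δω | 0.01 rad | per-ROI scatter that leaves bin-mean SEMs ~10⁻³ rad at screen scale, the regime in which the ±20 % Kd tolerance is meaningful |
| n_rois/replicate | 3000 | ≥ 20 ROIs in the sparsest (40–50 µM) bin under log-uniform sampling |
| E (FRET efficiency) | 0.3 | mid-range; `e_fret_for_delta_omega_max` inverts the Δω_max relation when a curve amplitude (e.g. 0.2 rad) is the natural parameter |

The photon-level generator (Poisson counts of a two-lifetime mixture) is
a separate path for exercising the phasor stage; note that phase angles
are not linear in the bound fraction, so a phasor computed from a mixed
decay differs slightly from the Δω_max·f idealisation used for the ROI
tables. The inference pipeline is agnostic to which path produced its
input.

What the generator does *not* emulate: detector IRF and afterpulsing,
pixel-level spatial correlation within ROIs, acceptor photophysics
(dark-state fractions), cell-to-cell Tau1 variation, and any dependence
of ROI frequency on expression level beyond the sampling law. Passing
tests therefore certify the inference chain under a faithful equilibrium
model with realistic counting statistics, not robustness to every
instrumental artifact.

## Binning, averaging, fitting, deciding

ROIs are gated to donor 1–3 µM and acceptor 0–50 µM, then binned by free
acceptor on edges 0, 2.5, 5, 7.5, 10, 15, 20, 25, 30, 40, 50 µM (the
range is prescribed; the edges are this suite's default and are
configurable). Each bin reports the mean Δω, SEM, count, and — as the
abscissa — the mean free-acceptor concentration of its ROIs rather than
the geometric bin center: under skewed within-bin sampling the bin
center biases the low-concentration points of the fitted curve (Jensen's
inequality on a concave curve), inflating Kd by tens of percent, while
the within-bin mean is unbiased to first order. Bins under 20 ROIs are
dropped with a log entry. Replicate curves (3 by default) are averaged
unweighted per bin; counts sum; SEMs combine in quadrature over the
replicates present.

Free acceptor is taken from the ROI table when present (the generator
records acceptor − bound exactly). When only totals are available the
approximation free ≈ total is adequate above ~5 µM since bound ≤ donor ≤
3 µM.

The Hill fit minimises the residual sum of squares over the bin means
with bounds Bmax ∈ [0, 1] rad, Kd ∈ (0, 500] µM, multi-start at Kd₀ ∈
{5, 15, 40} µM (Bmax₀ = max Δω); SEM weighting is a flag. Fits riding
the Bmax/Kd ridge (non-saturating data: either parameter pinned at its
bound with Kd beyond the sampled range) carry a `kd_at_bound` flag
rather than erroring. An optional linear background term c·x absorbs
residual collisional FRET at high acceptor; it is off by default — on
simulated data without a collision component the plain Hill fit is the
correct model, and the term is available for curves with a visible
upward tail. A residual-resampling bootstrap (200 draws) supplies an
optional percentile CI for Kd; no heavier uncertainty machinery is
attempted.

The s-ratio is computed on the averaged curve by trapezoid integration:
AUC of (Δω − Δω_min) over [x_min, x_max], divided by (box − AUC) where
box = (x_max − x_min)·(Δω_max − Δω_min). It is exactly 1 for collinear
points, invariant to affine rescaling of either axis, decreasing in Kd
for noiseless Hill curves on the screening range, and undefined (error)
for flat curves — the classifier catches that case and reports a
degenerate collision verdict instead of failing the run. The binding
verdict requires s-ratio ≥ 2 *and* fitted Bmax > 0.05 rad; everything
else is a collision, reported with its linear fit.

## Motif scanning

Alignment follows the EMBOSS-Needle-style configuration: global
Needleman–Wunsch, BLOSUM62, affine gaps, end gaps free, so a short BH3
query locates its best segment on a full-length protein while the
alignment stays global. The suite's gap convention is that a gap of
length L costs open + (L−1)·extend with open = 10, extend = 0.5; the
dynamic programming is delegated to Biopython's PairwiseAligner and is
verified in tests against exhaustive enumeration of all alignments for
sequences up to length 6. X is accepted and scored 0 against everything.
Percent identity defaults to the *core* denominator (columns from the
query's first to last aligned residue): against a ~7000-residue target
the full-alignment denominator is dominated by end gaps and cannot
express a meaningful motif identity.

The bundled Bax BH3 query is the 16-mer KKLSECLKRIGDELDS (h1 = L at
offset 2, h2 = L, h3 = I, h4 = L, conserved D at h3+2), i.e. residues
57–72 in UniProt Q07813 numbering.

The consensus pattern places h1/h2/h3/h4 at window offsets 0/4/7/11 and
the acidic slot at 9 (= h3+2). Slot sets: nonpolar {A,V,L,I,M,F,W,C}
for the h positions, with Thr additionally allowed at h2 (its branched
side chain still makes nonpolar contacts, and known BH3-like motifs
carry it there); {D,E,N,Q} at h3+2 (Asp canonical, the others
tolerable). h1 may be made optional, since characterised BH3-like motifs
exist that conserve only h2–h4. The scan is verified against a naive
regex re-scan as an independent oracle.

Amphipathicity: hydrophobic moment μH = |Σₙ H(aaₙ)·e^{i n δ}| at δ =
100°/residue, Eisenberg consensus scale shipped as default, any
user-supplied per-residue scale accepted. μH is reported both total and
per-residue; note it is *not* invariant to adding a constant to the
scale (the exact correction term c·Σₙe^{i n δ} is asserted in tests), so
scales should be compared only in their published normalisation.

`scan_report` merges alignment and consensus hits (overlaps deduplicated
in favour of the alignment hit, which carries an identity), annotates
μH, and ranks by identity then μH. Coordinates are 1-based inclusive in
the target's own (UniProt-style) numbering.

## Quantification statistics

Dot densities are counts per cell area in arbitrary pixel-like units —
every downstream quantity is a ratio, so no µm² calibration is needed.
Fold ratios are computed per independent experiment (mean treated
density / mean control density), and significance uses a paired
Student's t test on the natural-log ratios with the experiment as the
pairing unit; with a single ratio per experiment this is exactly the
one-sample t test of log(ratio) against 0. df = n−1 over the
experiments, not the cells — cells within an experiment are not
independent replicates of the treatment effect. Identical pairs give
t = 0, p = 1; a constant nonzero log-ratio has zero estimated variance
and is reported as t = ±∞ rather than masked. The two-sample test uses
the pooled-variance statistic; one-tailed p values are directional for
mean(a) > mean(b), hence exactly half the two-tailed p when t > 0.
Fraction-positive scoring takes a per-cell boolean (e.g. diffuse vs
punctate cytochrome c) supplied by the caller or the generator —
automated diffuse/punctate image classification is out of scope — and
enforces a 100-cell minimum cohort by default.

The dot detector is a minimal Laplacian-of-Gaussian local-maximum
finder with a robust (median + k·MAD) threshold, which makes the count
invariant to constant background offsets; maxima closer than the
minimum separation merge into one detection. It is intended for the
synthetic spot images produced alongside it, not as a general spot
caller for real micrographs. ROI segmentation for the FLIM channel is
Otsu thresholding followed by marker-based watershed on the distance
transform, minimum ROI size 20 px.

## Problem sizes and determinism

The shipped acceptance harness simulates 3 replicates × 3000 ROIs per
condition — enough for every default bin to clear the 20-ROI floor and
for bin-mean SEMs near 10⁻³ rad — and recovers Kd within a few percent;
the Monte-Carlo tests run 50 seeds per affinity. All randomness flows
through `numpy.random.default_rng` seeded from explicit integers;
replicate r of a dataset uses the stream seeded by (seed, r), so
datasets are byte-reproducible across platforms.

## Known limitations

* The Δω-vs-bound-fraction linearity in the ROI-table generator is an
  idealisation (exact only in the small-shift limit); the photon-level
  path quantifies the discrepancy but the two are not forced to agree.
* Only h = 1 Hill fits are offered; cooperative or multi-site models are
  out of scope, as is multi-harmonic phasor analysis.
* The motif scanner does not predict secondary structure; μH on the
  linear sequence is a proxy for helical amphipathicity.
* Statistical tests assume log-normality (paired test) or normality with
  equal variances (two-sample); no multiple-testing correction is
  applied.
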