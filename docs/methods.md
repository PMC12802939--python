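# Methods

This note documents the models, parameter choices and numerical decisions
behind each pipeline stage, what the synthetic generators do and do not
emulate, and the known limitations.

## Sequence model

Constructs are the canonical human telomeric 24-mer (TTAGGG)₄ with at most
one ribose-sugared residue, written in lowercase-r notation: `r` is a prefix
modifier that marks the next base and consumes no sequence position, so a
construct named for position *p* (TELR10 ↔ position 10) indexes the plain
base string. Positions are 1-based to match construct names.

The structural class of a substitution is a pure function of its offset
within the repeat, `(p − 1) mod 6`: offsets 0–1 → T, 2 → loop A, 3 → G1,
4 → G2, 5 → G3. Position 3 thereby classifies as a loop A even though, in
the folded structure, it sits on the 5′ flank before the first tetrad rather
than in an inter-tetrad loop; the classification follows the sequence-level
rule uniformly. T positions are accepted and labeled (not an error) even
though no published construct substitutes one.

## CD conformation calling

Each of the four intramolecular G4 topologies is represented as an extrema
signature (see README). Signatures are turned into model curves as sums of
unit-amplitude Gaussian bands, positive at maxima and negative at minima,
with a 12 nm band width (sigma). That width keeps the adjacent 265/290 nm
bands resolvable on the 1 nm grid while producing realistically smooth,
overlapping features; overlap pulls apparent peaks up to ~3 nm off the
nominal band centers, which is why extrema matching uses a ±8 nm tolerance
(published signature positions are themselves approximate, and observed
peaks drift several nm between constructs).

Calling combines two rules:

1. **Extrema matching.** Observed local extrema (after an optional moving
   average; the classifier applies a 9 nm window by default, emulating the
   noise suppression of averaging repeated scans) are matched against each
   signature; the score is the fraction of required extrema matched by an
   observed extremum of the correct kind within tolerance, and signatures
   scoring ≥ 0.75 pass. A passing signature whose matched extrema are a
   subset of a more specific passing signature's is pruned — a pure 3+1
   hybrid spectrum contains the complete parallel fingerprint and must not
   be called a mixture.
2. **Band decomposition.** The spectrum is decomposed by non-negative least
   squares onto the four model curves. When the reconstruction explains the
   spectrum (relative residual ≤ 0.3), the decomposition arbitrates: the
   call is the set of components holding ≥ 0.25 of the total weight. This
   is essential for mixtures whose components mask each other's extrema —
   in an even parallel + antiparallel-chair mixture the parallel +265 band
   and the chair −265 band cancel exactly, so neither component can reach
   the extrema threshold on its own — and it discards signatures that pass
   the extrema score only through spurious noise peaks. When the
   decomposition cannot explain the spectrum, the extrema-based call stands.

A spectrum with no detectable extremum returns an explicit unclassifiable
result rather than raising. With noise at 10% of peak amplitude the
combined rule recovers each pure topology in ≥ 95 of 100 seeded replicates
(measured 100/100), and resolves all four topology pairs observed as mixed
populations at even weights.

## Melting temperature

Tm is extracted exactly as in the wet-lab procedure: a least-squares cubic
*aT³ + bT² + cT + d* over the recorded ramp, with Tm the unique root of the
second derivative, −b/(3a). Two failure modes are reported as typed errors:
a leading coefficient carrying no curvature at the data scale (relative
threshold 1e−8, e.g. a straight-line ramp), and an inflection outside the
fitted window.

The fit window matters. On a symmetric two-state sigmoid a window centered
on the midpoint is unbiased; shifting the window center biases the cubic
inflection in the *opposite* direction (a window centered 5 °C below the
midpoint overestimates Tm by ~1.5 °C at the default transition width), and
windows centered far off the transition are unusable. The optional
auto-window therefore centers ±15 °C on the steepest-slope temperature,
which keeps the estimate within 1 °C of the true midpoint across midpoints
40–80 °C. The default remains the full 25–95 °C ramp, since the published
procedure fits each experiment without a stated window. Dual-wavelength
constructs are fitted once per wavelength; mixed-population melting is not
deconvolved (one Tm per curve). Tm is reported to 0.01 °C.

ΔTm is the plain difference of sample and reference Tm. Recomputing the
published shift column from the published Tm columns reproduces it to one
unit in the last printed digit (0.01 °C); the residual ulp discrepancies on
a few rows arise because the published shifts were computed from unrounded
replicate means.

## smFRET analysis

Efficiency is the uncorrected ratio E = I_A/(I_A + I_D) of acceptor and
donor emission under donor excitation; no leakage or gamma correction is
applied, matching the measurement definition. Frames with nonpositive total
intensity are dropped, not zero-filled.

Histograms pool every valid frame of every molecule over [−0.2, 1.2] with a
0.02 bin width (≈14 bins across ±1σ of a 0.14-wide peak). The peak is a
least-squares single Gaussian initialized at the mode, so a bimodal
histogram is fitted to its taller mode; the reported half-width is the
fitted sigma (multiply by √(2 ln 2) ≈ 1.177 for HWHM — the published
"half-width" column does not state its convention).

Trace classification binarizes frames at E ≥ 0.6 (the cutoff separating the
folded peak near 0.67 from the unfolded population centered at 0.4 with
spread up to 0.6). Because per-frame noise would relabel nearly every
molecule dynamic under a literal all-frames rule, only dwells of at least
`min_dwell` frames (default 5 = 0.5 s) count as genuine state visits;
shorter runs are absorbed into the surrounding visit. This "genuine-visit"
formulation is deliberately not an iterative shortest-run merge: merging can
coalesce a cluster of sub-dwell noise dips into a spurious ≥5-frame
excursion (measured: 86% ground-truth agreement for the iterative variant
vs 99.5% for the genuine-visit rule at default noise). A trace whose
genuine visits are all folded is static-folded, all unfolded is unfolded,
anything else dynamic with the number of surviving state changes reported.
A trace with no genuine visit at all (pathological flicker) falls back to
its majority state. The dwell filter is an explicit surrogate for manual
trace categorization, not the original authors' criterion.

Repeat summaries report per-repeat label percentages with mean and sample
SD (n − 1), treating experimental repeats as a sample.

## Cleavage analysis

Percent cleavage is cleaved/(cleaved + uncleaved) band intensity — scale
invariant, so unnormalized densitometry units are fine. Replicates sharing
a time grid aggregate to mean ± sample SD per timepoint; a replicate mean
below 0.1% is flagged not-detected (N.D.), mirroring assay floors.
Position-class summaries group constructs solely by the sequence model's
classification; N.D. entries enter class means as zero by default (an
undetectable product is ~0 cleavage; excluding it would bias class means
upward), and the policy is recorded in the output. The descriptive
first-order fit F(t) = burst + (plateau − burst)(1 − e^(−kt)) uses bounded
least squares (fractions in [0, 1], k ≥ 0) with tight convergence
tolerances; exactly flat series short-circuit to k = 0 with burst = plateau
= the constant level. Cation comparison is a plain Na⁺ − K⁺ mean-difference
table — the underlying experiments report descriptive statistics only, so
no hypothesis test is attached.

## Synthetic generators

All generators are deterministic given (seed, parameters) and expose every
ground-truth parameter through `SyntheticConfig`. Defaults encode the study
conditions: 220–340 nm spectra at 1 nm pitch; 25–95 °C ramps at 1 °C with a
3 °C logistic transition width; 100 ms frames, 180 s trace records and 2 s
histogram movies; folded emission mean 0.67 and unfolded 0.4 with 0.05
Gaussian emission noise; trace-type fractions (0.743, 0.178, 0.079); and a
{1, 5, 15, 30, 60, 120} min cleavage grid. Dynamic molecules follow a
two-state discrete-time Markov chain with per-frame switch probabilities
1 − e^(−k·Δt), started from the stationary distribution; the switching
rates (0.2/s folded→unfolded, 0.3/s unfolded→folded, i.e. dwells of 5 s and
3.3 s) are not published quantities — they were chosen once so that dynamic
molecules show several transitions per record while dwells stay well above
the classifier's excursion filter. Donor/acceptor intensities are
reconstructed as acceptor = scale·E and donor = scale·(1 − E), so the
efficiency formula inverts the generator exactly.

Deliberately not modeled: photobleaching, blinking, shot noise and camera
offsets; spectral crosstalk and gamma; intermolecular G4 species;
three-state folding intermediates; gel densitometry itself (band
intensities are the input). Noise is Gaussian throughout, truncated where
physical bounds apply (band intensities ≥ 0). Consequently, passing
recovery tests demonstrates that the analysis inverts data obeying its own
assumptions at realistic noise levels — not that it is robust to every
artifact of real instrument data.

## Problem sizes

The test suite and the reproduction script use the study-scale problem
sizes where they are cheap (6000 molecules × 20 frames for histograms, 1000
× 1800-frame traces for classification, 100 seeded replicates for noisy CD
recovery) and smaller sizes for property tests (e.g. 5 repeats × 200 traces
at 30 s records for repeat-summary recovery), chosen so the whole suite
runs in a few seconds on one CPU.
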