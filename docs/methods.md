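# Methods

This note documents the models and numerical choices behind `shiftbench`:
what is simulated, how spectra are compared, how predictors are scored, what
the synthetic data generator does and does not emulate, and where the design
was genuinely open.

## Spectrum representation

A spectrum is a vector of non-negative intensities on a uniform ppm grid in
descending-ppm order (index 0 at the high-frequency edge), the convention of
NMR display.  The default window is 20.693 ppm centred at 6.175 ppm —
ppm ∈ [−4.1715, 16.5215] — with 1024 points, matching a routine 250 MHz
acquisition binned to 1024 real points.  Negative intensities (baseline
artifacts) are clipped to zero on load and the count logged, because the
centre-of-mass summaries below require non-negative mass.  Binning uses
half-open bins with the final bin closed, so every point lands in exactly one
bin and total intensity is conserved exactly; normalisation rescales to unit
total with the last bin absorbing float rounding.

## Spectrum simulation

Predictions are lists of proton groups: chemical shift δ (ppm), number of
equivalent protons, and optional couplings (J in Hz with a partner count).
Multiplets are first order only: each coupling to *n* equivalent spin-½
partners splits every line into *n* + 1 lines with binomial weights at
spacing J/field ppm, symmetric about the shift.  Second-order (roofing)
effects are deliberately out of scope; the positional and intensity
information the similarity consumes is preserved, and the module boundary
allows a drop-in upgrade.

Each stick is convolved with a Lorentzian lineshape (Gaussian available) of
1.0 Hz FWHM, a typical linewidth at 250 MHz.  **Discretisation is by exact
bin integration**: a stick deposits into each bin the analytic integral of
its lineshape over that bin (arctan form for the Lorentzian, erf for the
Gaussian), with bins centred on the grid points.  Point-sampling the
lineshape at bin centres would be unsound here: the default linewidth
(0.004 ppm) is narrower than the grid step (0.0202 ppm), so sampled line
areas would depend on the sub-bin position of the line by a factor of up to
~2.5, which after normalisation corrupts the relative integrals of the proton
groups — the very quantity multiplet intensities encode.  Bin integration
keeps group integrals exact (a 2H group carries exactly twice the area of a
1H group), conserves total mass, and makes the centre of mass of a peak's
bins move linearly with the true line position, recovering sub-bin
information.  The output is normalised to unit total; if every stick lies
more than 50 linewidths outside the window, the spectrum is indistinguishable
from zero and the simulation raises a degenerate-input error instead.

## Tree similarity

Each spectrum (normalised, then thresholded by a noise floor that zeroes
intensities below 0.005 × the maximum) is summarised by a binary tree:

* the root covers the full window and every node stores its region, its
  **mass** (fraction of total intensity) and its intensity-weighted **centre
  of mass** (com);
* a node splits at its com into a high-ppm child (grid centres strictly above
  the com) and a low-ppm child, the two regions tiling the parent exactly;
* recursion stops at `max_depth` (8), below `min_mass` (0.01), below
  `min_width` (2 grid steps), or when the com coincides with a region edge
  (all mass at a boundary point, where a split makes no progress).

Signal-rich regions are therefore resolved deeply while blank or noisy zones
terminate immediately as low-mass leaves.

Node similarity is `exp(−|Δcom|/α) · min(m₁,m₂)/max(m₁,m₂)` with α = 0.1 ppm:
1 exactly when com and mass agree, decaying smoothly with com displacement
and mass mismatch.  Two empty nodes match perfectly; an empty node never
matches a non-empty one.  Tree similarity is defined recursively: for two
internal nodes,

    S(a, b) = w · node_sim(a, b) + (1 − w) · ½ (S(a_L, b_L) + S(a_R, b_R))

with level weight w = 0.5 (equal weight to the current level and to the
structure one level deeper).  Two leaves compare as nodes.  When only one
side has children, the leaf is compared as a node against each child subtree,
so a region that stops splitting in one spectrum degrades smoothly instead of
scoring zero.  The result is a convex combination of node kernels, hence in
[0, 1], symmetric, and 1 for identical trees.

All constants (`max_depth`, `min_mass`, `min_width`, `level_weight`,
`com_scale`, `noise_floor`) are exposed in `TreeParams` and serialisable to
YAML.  The binning baseline — cosine similarity of n-bin normalised profiles
— is provided for comparison.  On synthetic retrieval at 0.02 ppm prediction
noise both methods are near-perfect; from 0.05 ppm upward the tree similarity
retains a substantially higher MRR than 256-bin cosine, because the com
kernel degrades smoothly with displacement where binning collapses once lines
cross a bin edge.

## Benchmark statistics

The similarity matrix has experimental spectra as rows and simulated spectra
as columns, both in one molecule order, so entry (i, i) is the correct match
of query i.  Ranks use the pessimistic tie rule — the correct match takes the
worst position among ties, i.e. rank = #{j : S(i,j) ≥ S(i,i)} — which makes
MRR conservative and deterministic.  By default experimental spectra query
the simulated database; the reverse direction is a flag.  Reported per
predictor: MRR, the cumulative correct-match curve (n = 1 … n_max, default
20), and the accuracy-plane decomposition with absolute component
(s_best + s_correct)/√2 and relative component (s_best − s_correct)/√2,
reported in these raw projection units without renormalisation.  When
assigned shifts are supplied, the |observed − predicted| errors are pooled
and binned on 0.1 ppm intervals up to 0.35 ppm plus an overflow bin, with the
cumulative form also reported.

## Synthetic data generator

The generator emulates the *structure* of a predictor benchmark, not its
chemistry: molecules are shift lists, not structures.  Defaults per molecule:
2–8 proton groups, shifts i.i.d. uniform on 0.5–9.5 ppm, 1–3 equivalent
protons per group (equal weights), one coupling with probability 0.5 with J
uniform on 2–12 Hz and 1–3 partners.  "Experimental" spectra are simulations
plus zero-mean uniform noise with peak-to-peak amplitude `noise` × the
maximum intensity (how a spectroscopist quotes baseline noise against the
tallest peak), clipped at zero and renormalised; the default 0.01 puts the
noise ceiling at the default tree noise floor, as real baseline noise sits
near the threshold a practitioner would choose.  "Predictions" add i.i.d.
Gaussian noise N(0, σ²) to every shift, with σ spanning the error scale of
real predictors (up to ~0.35 ppm).  Truth generation, prediction
perturbation, and spectral noise draw from three independent RNG streams
keyed off one seed, so sweeps over σ share identical ground truths — paired
comparisons that reduce variance in monotonicity checks.

What passing synthetic tests does **not** show: robustness to real-data
features the generator omits — solvent and impurity peaks, baseline drift,
second-order multiplet distortion, correlated (systematic) predictor errors,
and realistic shift clustering (real spectra crowd the 1–4 and 6.5–8.5 ppm
regions).  Results on real data will depend on those factors; the synthetic
benchmark validates the machinery and its relative orderings, not absolute
MRR levels.

## Numerical choices and degenerate inputs

* Zero-total spectra are rejected (degenerate input), as are all-noise
  spectra after the noise floor.
* Similarity of spectra on different grids or windows is an argument error;
  no resampling is attempted.
* Tie-breaks: ranks are pessimistic (above); the binning assignment of a
  point exactly on a bin edge goes to the lower-ppm bin (half-open bins).
* Tree structure guards: a child with zero mass gets the region midpoint as
  its com; recursion never splits a region whose com sits on its edge.
* Simulation is fully deterministic; identical inputs give bit-identical
  spectra.

## Problem sizes

The test suite and the reproduction script run the pipeline at 20–100
molecules per benchmark and 3–20 seeded replicates, sizes at which every
statistic is stable enough for the orderings under test while a full run of
the suite stays in the minutes range on one CPU.  The similarity matrix is
the O(n²) step; matrices at n = 1000 (the scale of a real predictor
benchmark) take on the order of a minute, which is why the CLI decouples
matrix computation from plotting.

## Known limitations

* First-order multiplets only; strongly coupled spin systems simulate
  incorrectly (as they do in any first-order treatment).
* The tree constants are declared defaults, not values fitted to any real
  dataset; on real spectra α (com kernel scale) and the noise floor are the
  parameters most worth revisiting.
* The accuracy-plane components are reported in √2-scaled projection units,
  not renormalised to [0, 1]; only comparisons between predictors on the same
  dataset are meaningful.
* No phasing, baseline correction, solvent suppression or peak picking is
  performed; inputs are assumed to be processed spectra.
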