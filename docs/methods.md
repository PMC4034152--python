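# Methods

## Spectral model and canonical grid

All computation happens on a single uniform wavenumber grid, ascending
600–4000 cm⁻¹ with a 2 cm⁻¹ step (1701 points). FTIR instruments of the
class modelled here acquire at 4 cm⁻¹ optical resolution; a 2 cm⁻¹
digitization is the usual ≥2× oversampling and makes every diagnostic
window an integer point count. Input spectra (wide CSV or the minimal
JCAMP-DX subset) are validated, oriented ascending and linearly
interpolated onto this grid at construction; extrapolation is refused — a
spectrum must cover the full canonical range or the sample is rejected,
because inventing absorbance outside the measured range would silently
corrupt the window features. Windows are inclusive at both endpoints, and
an off-grid endpoint (e.g. 1575 cm⁻¹ on the 2 cm⁻¹ grid) snaps to the
nearest grid point, rounding half-intervals away from the window start.

## Preprocessing

The clustering features are the Savitzky–Golay second derivative
(`sg_points = 17`, `sg_polyorder = 3`, derivative with respect to
wavenumber, i.e. divided by step²) of the absorbance, sliced to the
diagnostic windows, concatenated in descending-wavenumber order, then
mean-centered and scaled to unit Euclidean norm. Choices worth recording:

* **Polynomial order 3.** A 17-point window fixes the smoothing span; order
  3 is the common choice for second derivatives that does not displace band
  maxima. Both are config-exposed.
* **Normalization after windowing.** "Vector normalized second derivative"
  fixes the order derivative → normalize but not the region; normalizing
  the final concatenated feature makes the clustering input scale-free,
  which is the point of the step. Normalizing each window separately is the
  plausible alternative; it was not adopted because it changes the relative
  weight of the sparse fatty-acid window.
* **Window sets.** The default `hca` region (3000–2800 ∪ 1700–600
  cm⁻¹) is what the dendrogram is computed from; the five functional-group
  windows (`functional5`: 3000–2800, 1700–1600, 1575–1300, 1200–900, 900–600)
  are provided as a named alternative. The two differ in the gaps
  1600–1575 and 1300–1200 cm⁻¹.
* **Edge handling.** One-sided polynomial fits at the grid ends (no
  reflection padding); no data are fabricated at 600/4000 cm⁻¹.
* Baseline correction is deliberately absent: the second derivative already
  annihilates constant and linear baselines, which is why it is used.

## Ward clustering and heterogeneity

Distances are Euclidean between normalized features; linkage is Ward's
minimum variance in the ward.D2 convention (heights in distance units,
h = √(2·ΔSSE); scipy's implementation, cross-checked in the test suite
against an exhaustive from-scratch ΔSSE recomputation on all small random
instances). "Heterogeneity" of a cluster is the height of its root merge —
the quantity dendrogram software displays. A `ward_d` variant (the same
recursion on unsquared distances) exists for sensitivity checks only.
Cuts undo the last k − 1 merges; clusters are labelled by majority species
with alphabetical tie-breaking (logged), and accuracy is
1 − misassigned/n. The dendrogram exports as Newick with ultrametric
branch lengths (node depth = merge height / 2).

## Fourier self-deconvolution

FSD assumes bands are intrinsically Lorentzian with full width Γ
(`band_fwhm`, default 12 cm⁻¹). The interferogram (real FFT of the
spectrum, after removing the endpoint ramp that the periodic DFT would
otherwise wrap) decays as exp(−πΓ|t|) for such a band; multiplying by
exp(+πΓ(1−1/K)|t|) converts it to a Lorentzian of width Γ/K
(`enhancement` K, default 2). An apodization window — Bessel-type
(1−u²)² by default; triangle, triangle², boxcar available — truncates the
growing weight at the point where its own transform has FWHM equal to one
third of the removed width Γ(1−1/K), which caps the weight at a constant
independent of Γ and K and keeps the apodization broadening well below the
residual bandwidth. Properties that follow, all asserted in tests: K → 1
is the exact identity; a matched 12 cm⁻¹ Lorentzian narrows to ≈ 6.5 cm⁻¹
at K = 2 (within 15 % of Γ/K); the integrated area of an isolated band is
preserved within 2 % (the t = 0 weight is one); and the unresolved
β-sheet doublet at 1627/1618 cm⁻¹ (FWHM 16, single raw maximum) splits
into two maxima at K = 2.5. The Bessel window is the default because the
steeper-tapering triangle² window broadens the K = 2 result past 7 cm⁻¹.
A weight exceeding 10⁶ raises an error recommending a smaller K.

## Peak picking and band comparison

Band positions are local minima of the SG second derivative (band maxima
of the raw spectrum), making the picking baseline-independent and
invariant to positive scaling. Within a window, minima with depth ≥
`rel_threshold` (default 0.1) of the deepest minimum are peaks; depths
between 0.05 and `rel_threshold` of the deepest are recorded as shoulders
(descriptive only — never used for clustering). Minima closer than
`min_separation` (default 6 cm⁻¹) merge keeping the deeper, ties keeping
the higher wavenumber. Two peak lists are compared by greedy
nearest-neighbour matching within a tolerance of 4 cm⁻¹ — the instrument
resolution, below which two bands are indistinguishable — closest pairs
first, distance ties resolved toward higher wavenumbers symmetrically;
unmatched peaks are "supplementary" to their own group. The cellulose
screen picks bands over 1700–1100 cm⁻¹ and flags contamination when at
least 3 of the 4 cellulose markers (1641, 1427, 1335, 1160 cm⁻¹) match:
root-tip spectra dominated by plant tissue show all four, fungal-mantle
spectra at most a coincidental one (the glycogen shoulder at 1161 cm⁻¹).

## Synthetic data generator

The generator emulates the field study the analysis was designed for —
its species, sampling design and published band inventory — because the
original spectra were never deposited.

* **Band templates** (`data/band_templates.csv`): per species, a list of
  (center, FWHM, relative amplitude, shape, assignment). Centers are the
  published inventory: shared cell-wall bands (chitin 1373/1154/1003,
  β-1,3-glucan 1031 with 1075-shoulder, shifted to 1090 in
  *A. rubescens*), lipid bands (2925/1451 in all; 1370 in all but
  *X. pruinatus*; 2850/1740 only in the two Russulaceae), tyrosine 1515,
  amide I maxima 1632/1630/1633/1617 and the *R. ochroleuca*
  1627 + 1618 + 1649 triplet, the α-helix doublet 1548/1542 only in
  *X. pruinatus* and *A. rubescens*, glycogen shoulders 1153 vs 1161, and
  the *C. geophilum* markers 1108 and 831 together with its missing
  990/976 mannan shoulders. Widths (16 cm⁻¹ broad amide/polysaccharide
  bands, 10 cm⁻¹ sharp) and relative amplitudes are model choices, not
  measurements; amplitudes follow class values (amide I 1.0,
  polysaccharide majors 0.8, lipid CH stretch 0.6, minor/shoulder bands
  0.2–0.4) calibrated once so the default-noise pipeline reproduces the
  ≥ 97 % discrimination and the phylum-level split, and then frozen in the
  packaged table. Lorentzian lineshapes by default (condensed-phase ATR).
* **Environment modifiers** enter at 0.5 × their class amplitude, so
  environmental effects are real but weaker than species identity — the
  study's central finding. Mixed-stand additions: *C. geophilum*
  {2363, 1663, 1453, 1372, 830}, *X. pruinatus* {1313}, *A. rubescens*
  {1544, 1372} (mono-stand marker 1407); Swabian *C. geophilum* adds
  {1621, 1234}. Because the five *C. geophilum* mixed-stand bands are
  described as completely absent from mono-stand samples, the mono context
  also removes the overlapping core bands 1451/1373/1370/831. Host tree
  affects metadata only.
* **Within-species variability**: per-band center jitter N(0, 1.5 cm⁻¹)
  and log-normal amplitude scatter (CV 0.20, unit mean), a random
  quadratic baseline (coefficient scale 0.01 absorbance) and i.i.d.
  detector noise (sd 0.002 absorbance). These values are plausible for
  replicate biological ATR measurements but are assumptions — the real
  within-species covariance is unknown. A `low_variability` preset
  (jitter 0.5, CV 0.05, noise 0.001) is the condition for group-mean band
  comparisons, where center jitter would otherwise blur the weakest
  shoulders in small groups.
* **Composition**: the study's 181 samples — *A. rubescens* 7 mono +
  10 mixed, *C. geophilum* 4 mono + 40 mixed + 17 Swabian, *L. subdulcis*
  32 + 35, *R. ochroleuca* 13 mono, *X. pruinatus* 21 + 2 — with the
  non-beech host trees (lime, hornbeam) placed in the mixed stands.
* **Reproducibility**: sample i always draws from the counter-based RNG
  substream (seed, i), so spectra are bit-reproducible and independent of
  composition order.

What passing tests on this generator do and do not show: they demonstrate
that the pipeline recovers the structure the generator encodes (species
band patterns stronger than environment effects, distinctive ascomycete
chemistry) at realistic noise; they cannot validate performance against
instrument artifacts absent from the model — ATR penetration-depth
dispersion, water-vapour and CO₂ lines, scattering baselines, or
correlated biochemical variation between bands.

## Numerical choices and degenerate inputs

Constant spectra cannot be vector-normalized (error, not NaN). Ward
tie-breaks in the oracle take the lexicographically smallest index pair;
ties are measure-zero for continuous features. Majority-label ties break
alphabetically with a logged warning. Peak picking returns an empty list
on flat windows; a band centered exactly between two grid points reports
either neighbour (both within one grid step). `heterogeneity_ratio`
requires each group to be exactly the leaf set of a tree node; the
Swabian analysis therefore evaluates the largest all-Swabian subtree,
mirroring how a sub-cluster is read off a dendrogram. Report floats are
serialized at 12 significant digits; rerunning a configuration reproduces
the report bit for bit.

## Problem sizes

The shipped analyses use the full 181-sample composition (seconds per
run); robustness sweeps use 10 seeds × 3 noise levels. The Ward oracle
cross-check runs 100 random instances at n ≤ 8, where exhaustive ΔSSE
recomputation is exact and cheap.

## Known limitations

* Real mid-IR spectra of mycorrhizal mantles contain broad OH/NH stretch
  envelopes (3600–3000 cm⁻¹) that the templates omit; the clustered
  windows exclude that region, so the omission does not affect the
  pipeline's conclusions.
* The 1.5× Russulaceae similarity factor and the 7.8× Swabian sub-cluster
  heterogeneity ratio of the original field data are magnitudes of real
  biological variation; the synthetic data only reproduce their direction
  (a tighter Swabian subgroup, ratio < 1), not their size.
* The JCAMP-DX reader covers the AFFN `(X++(Y..Y))` and `XYPOINTS`
  dialects only; compressed encodings (SQZ/DIF/DUP) are rejected with an
  explicit error.
* FSD parameters of the original analysis are unknown; the defaults here
  (Γ = 12 cm⁻¹, K = 2, Bessel apodization) are textbook values, and peak
  inventories on deconvolved means should be read as qualitative.
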