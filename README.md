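# ectospec

Identification of ectomycorrhizal (ECM) fungi on tree root tips from
ATR-FTIR spectra of the outer hyphal mantle.

Forest trees host dozens of ECM fungal species whose identity is tedious to
establish by morphotyping and ITS sequencing. Because attenuated total
reflectance FTIR only probes the outermost ~2 µm of a root tip — exactly
the fungal mantle — the infrared absorbance spectrum is a biochemical
fingerprint of the fungus itself (cell-wall chitin and β-1,3-glucans,
taxon-variable mannans, lipids, protein secondary structure). `ectospec`
implements the complete chemometric workflow for turning such spectra into
species assignments, plus a synthetic-spectrum generator that reproduces
the statistical structure of a five-species field study (181 root-tip
spectra of *Amanita rubescens*, *Cenococcum geophilum*, *Lactarius
subdulcis*, *Russula ochroleuca* and *Xerocomus pruinatus* from
mono-specific beech, mixed deciduous and Swabian-Jura stands), so that the
entire analysis is runnable and testable without access to the original
instrument data.

## Method

For each spectrum A(ν) on the canonical grid (600–4000 cm⁻¹, 2 cm⁻¹ step):

1. **Second derivative** d²A/dν² by Savitzky–Golay filtering (17 points,
   cubic), removing additive baselines and sharpening overlapped bands.
2. **Windowing** to the diagnostic regions actually clustered
   (3000–2800 ∪ 1700–600 cm⁻¹; the five functional-group windows are
   available as the `functional5` configuration), concatenated in
   descending-wavenumber order.
3. **Vector normalization**: x ← (x − x̄)/‖x − x̄‖₂, making features
   invariant to the contact-pressure intensity scale.
4. **Ward hierarchical clustering** on Euclidean distances (ward.D2
   convention: merge height h = √(2·ΔSSE), displayed as "heterogeneity"),
   with k-cuts, majority-species labelling and misassignment scoring.
5. **Band-level analysis**: Fourier self-deconvolution
   (interferogram reweighting by exp(+πΓ(1−1/K)|t|) with a Bessel-type
   apodization window; Γ = assumed intrinsic Lorentzian FWHM, K = narrowing
   factor), second-derivative peak picking, a cellulose contamination
   screen (markers 1641, 1427, 1335, 1160 cm⁻¹), and supplementary/missing
   band comparison between sample groups.

## Worked example

```python
import ectospec as es

run = es.run_pipeline(es.RunConfig())   # 181 synthetic spectra, seed 42
print(run.n_samples, run.accuracy, run.phylum_split_ok)
```

prints `181 0.994475138121547 True`: at k = 5, 180 of the 181 spectra land
in the cluster of their own species (99.4 % discrimination; the field
benchmark is 97 %), and the k = 2 cut separates the ascomycete
*C. geophilum* from the four basidiomycetes exactly. The same run exposes
the environment contrast on deconvolved group means
(`run.environment_comparisons`): the *C. geophilum* mixed-stand mean gains
bands at 2364, 1664, 1452, 1372 and 830 cm⁻¹ that its mono-stand mean
lacks, while *L. subdulcis* shows no environment signal — the
litter-confined fungus against the wide-niche ones.

The numbered drivers under `analysis/` run the same steps as a narrative
(`01` simulate, `02` cluster, `03` species band signatures,
`04` environment comparison, `05` noise robustness) and write their tables
under `results/`. For example `python analysis/02_cluster_species.py`
prints:

```
n_samples        181
accuracy (k=5)   0.9945  (1 misassigned)
phylum split ok  True  (k=2 cut isolates C. geophilum)
Swabian subtree  11/17 samples, heterogeneity ratio vs species cluster 0.393
```

## Layout

```
src/ectospec/    io, preprocess, bands, cluster, simulate, pipeline
src/ectospec/data/band_templates.csv   the per-species band inventory
analysis/        numbered narrative drivers
tests/           pytest suite (unit, property and acceptance tests)
scripts/acceptance.py
docs/methods.md  model assumptions, parameter choices, limitations
```
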