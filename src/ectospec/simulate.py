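"""Synthetic ATR-FTIR spectrum generator for ectomycorrhizal root tips.

Field spectra of the five ECM species were never deposited, so this module
generates labelled stand-ins with the statistical structure the analysis
assumes: each species is a published inventory of infrared bands
(Lorentzian by default — the usual condensed-phase ATR lineshape), some
shared across fungi (chitin, β-1,3-glucan, lipid, tyrosine), some
species-specific (amide I maxima between 1617 and 1633 cm⁻¹, mannan-region
markers, the Russulaceae-only 2850/1740 cm⁻¹ lipid pair).  Forest type and
site add or remove modifier bands at half the corresponding class
amplitude, encoding the study design in which environmental effects are
real but weaker than species identity.  Host tree affects metadata only.

Within-species biochemical variability is modelled as per-band center
jitter and log-normal amplitude scatter, plus a random quadratic baseline
and white detector noise.  Every sample draws from its own counter-based
RNG substream, so a sample's spectrum does not depend on the composition
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .io import CANONICAL_GRID, SampleMeta, SpectralDataset, Spectrum, WavenumberGrid

__all__ = [
    "BandTemplate",
    "SpeciesTemplate",
    "CompositionEntry",
    "GeneratorConfig",
    "DEFAULT_COMPOSITION",
    "SPECIES_ABBREV",
    "builtin_templates",
    "template_spectrum",
    "generate_spectrum",
    "generate_dataset",
    "generate_cellulose_spectrum",
]

SPECIES_ABBREV = {
    "Amanita_rubescens": "Ar",
    "Cenococcum_geophilum": "Cg",
    "Lactarius_subdulcis": "Ls",
    "Russula_ochroleuca": "Ro",
    "Xerocomus_pruinatus": "Xp",
}

#: Bands every species template must carry (cell-wall core + shared lipid
#: and protein markers); the glucan shoulder may sit at 1075 or 1090 cm⁻¹.
_SHARED_REQUIRED = (1031.0, 1373.0, 1154.0, 1003.0, 2925.0, 1451.0, 1515.0)


@dataclass(frozen=True)
class BandTemplate:
    center: float
    fwhm: float
    amplitude: float
    shape: str = "lorentzian"  # "lorentzian" | "gaussian"
    assignment: str = ""

    def __post_init__(self) -> None:
        if not 600.0 <= self.center <= 4000.0:
            raise ValueError(f"band center {self.center} outside 600–4000 cm⁻¹")
        if self.fwhm <= 0 or self.amplitude <= 0:
            raise ValueError("band fwhm and amplitude must be positive")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def evaluate(self, wn: np.ndarray, center: float | None = None,
                 amplitude: float | None = None) -> np.ndarray:
        c = self.center if center is None else center
        a = self.amplitude if amplitude is None else amplitude
        if self.shape == "lorentzian":
            hwhm2 = (self.fwhm / 2.0) ** 2
            return a * hwhm2 / ((wn - c) ** 2 + hwhm2)
        return a * np.exp(-4.0 * np.log(2.0) * (wn - c) ** 2 / self.fwhm**2)


@dataclass(frozen=True)
class SpeciesTemplate:
    species: str
    core_bands: tuple[BandTemplate, ...]
    additions: Mapping[str, tuple[BandTemplate, ...]] = field(default_factory=dict)
    removals: Mapping[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        centers = {b.center for b in self.core_bands}
        missing = [c for c in _SHARED_REQUIRED if c not in centers]
        if missing:
            raise ValueError(
                f"{self.species}: core bands missing shared centers {missing}"
            )
        if not ({1075.0, 1090.0} & centers):
            raise ValueError(f"{self.species}: glucan shoulder (1075/1090) missing")
        for ctx, removed in self.removals.items():
            orphan = [c for c in removed if c not in centers]
            if orphan:
                raise ValueError(
                    f"{self.species}/{ctx}: removals {orphan} reference no core band"
                )

    def bands_for(self, context: str | None,
                  modifier_amplitude_scale: float = 1.0) -> tuple[BandTemplate, ...]:
        """Core bands with the context's removals and (scaled) additions.

        ``context=None`` returns the core inventory unchanged.
        """
        if context is None:
            return self.core_bands
        removed = set(self.removals.get(context, ()))
        bands = [b for b in self.core_bands if b.center not in removed]
        bands += [
            replace(b, amplitude=b.amplitude * modifier_amplitude_scale)
            for b in self.additions.get(context, ())
        ]
        return tuple(sorted(bands, key=lambda b: -b.center))


@dataclass(frozen=True)
class CompositionEntry:
    species: str
    site: str
    forest_type: str
    host_tree: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("composition counts must be >= 0")


#: The study's sample composition: 181 root-tip spectra across mono-specific
#: beech stands, mixed deciduous stands (Hainich), and a Swabian beech site;
#: host trees other than beech occur only in the mixed stands.
DEFAULT_COMPOSITION: tuple[CompositionEntry, ...] = (
    CompositionEntry("Amanita_rubescens", "Hainich", "mono", "beech", 7),
    CompositionEntry("Amanita_rubescens", "Hainich", "mixed", "beech", 5),
    CompositionEntry("Amanita_rubescens", "Hainich", "mixed", "hornbeam", 5),
    CompositionEntry("Cenococcum_geophilum", "Hainich", "mono", "beech", 4),
    CompositionEntry("Cenococcum_geophilum", "Hainich", "mixed", "beech", 29),
    CompositionEntry("Cenococcum_geophilum", "Hainich", "mixed", "lime", 8),
    CompositionEntry("Cenococcum_geophilum", "Hainich", "mixed", "hornbeam", 3),
    CompositionEntry("Cenococcum_geophilum", "Swabian", "mono", "beech", 17),
    CompositionEntry("Lactarius_subdulcis", "Hainich", "mono", "beech", 32),
    CompositionEntry("Lactarius_subdulcis", "Hainich", "mixed", "beech", 33),
    CompositionEntry("Lactarius_subdulcis", "Hainich", "mixed", "lime", 2),
    CompositionEntry("Russula_ochroleuca", "Hainich", "mono", "beech", 13),
    CompositionEntry("Xerocomus_pruinatus", "Hainich", "mono", "beech", 21),
    CompositionEntry("Xerocomus_pruinatus", "Hainich", "mixed", "beech", 2),
)


@dataclass(frozen=True)
class GeneratorConfig:
    composition: tuple[CompositionEntry, ...] = DEFAULT_COMPOSITION
    center_jitter_sd: float = 1.5  # cm⁻¹
    amplitude_cv: float = 0.20
    noise_sd: float = 0.002  # absorbance units
    baseline_degree: int = 2
    baseline_scale: float = 0.01
    modifier_amplitude_scale: float = 0.5
    seed: int = 42

    def noiseless(self) -> "GeneratorConfig":
        return replace(
            self, center_jitter_sd=0.0, amplitude_cv=0.0, noise_sd=0.0,
            baseline_scale=0.0,
        )

    def low_variability(self) -> "GeneratorConfig":
        """Low biochemical/instrumental variability: the condition under
        which group-mean band inventories are compared across environments."""
        return replace(
            self, center_jitter_sd=0.5, amplitude_cv=0.05, noise_sd=0.001,
        )


def builtin_templates() -> dict[str, SpeciesTemplate]:
    """Load the packaged per-species band-assignment table.

    Band positions are transcribed from published ECM mantle spectra;
    widths (16 cm⁻¹ broad amide/polysaccharide bands, 10 cm⁻¹ sharp bands)
    and relative amplitudes are model choices, not measurements.
    """
    with resources.files("ectospec.data").joinpath("band_templates.csv").open() as fh:
        table = pd.read_csv(fh)
    templates: dict[str, SpeciesTemplate] = {}
    for species, rows in table.groupby("species", sort=True):
        core: list[BandTemplate] = []
        additions: dict[str, list[BandTemplate]] = {}
        removals: dict[str, list[float]] = {}
        for _, row in rows.iterrows():
            band = BandTemplate(
                center=float(row["center_cm1"]),
                fwhm=float(row["fwhm_cm1"]),
                amplitude=float(row["rel_amplitude"]),
                shape=str(row["shape"]),
                assignment=str(row["assignment"]),
            )
            ctx = str(row["context"])
            if ctx == "core":
                core.append(band)
            elif ctx.endswith("_add"):
                additions.setdefault(ctx[: -len("_add")], []).append(band)
            elif ctx.endswith("_remove"):
                removals.setdefault(ctx[: -len("_remove")], []).append(band.center)
            else:
                raise ValueError(f"unknown template context {ctx!r}")
        templates[str(species)] = SpeciesTemplate(
            species=str(species),
            core_bands=tuple(sorted(core, key=lambda b: -b.center)),
            additions={k: tuple(v) for k, v in additions.items()},
            removals={k: tuple(v) for k, v in removals.items()},
        )
    return templates


def context_key(site: str, forest_type: str) -> str:
    """Modifier context of a sample: the Swabian site overrides forest type."""
    return "swabian" if site == "Swabian" else forest_type


def template_spectrum(
    species: str,
    context: str | None = None,
    templates: Mapping[str, SpeciesTemplate] | None = None,
    grid: WavenumberGrid = CANONICAL_GRID,
    modifier_amplitude_scale: float = 0.5,
) -> Spectrum:
    """Noiseless spectrum of a species template (pure band sum)."""
    tmpl = (templates or builtin_templates())[species]
    wn = grid.wavenumbers
    y = np.zeros_like(wn)
    for band in tmpl.bands_for(context, modifier_amplitude_scale):
        y += band.evaluate(wn)
    meta = SampleMeta(
        sample_id=f"{SPECIES_ABBREV.get(species, species)}_template"
        + (f"_{context}" if context else ""),
        species=species,
        forest_type=context if context in ("mono", "mixed") else "unknown",
        site="Swabian" if context == "swabian" else "unknown",
    )
    return Spectrum(grid, y, meta)


def _sample_rng(seed: int, index: int) -> np.random.Generator:
    """Counter-based substream: independent of composition order."""
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def generate_spectrum(
    tmpl: SpeciesTemplate,
    context: dict[str, str],
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    grid: WavenumberGrid = CANONICAL_GRID,
    sample_id: str | None = None,
) -> Spectrum:
    """Draw one noisy spectrum for a template in a given field context.

    ``context`` needs keys ``site``, ``forest_type`` and optionally
    ``host_tree`` (metadata only).  Per band: center ± N(0, jitter),
    amplitude × LogNormal(mean 1, CV), then quadratic baseline drift and
    i.i.d. detector noise.
    """
    ctx = context_key(context["site"], context["forest_type"])
    bands = tmpl.bands_for(ctx, cfg.modifier_amplitude_scale)
    wn = grid.wavenumbers
    y = np.zeros_like(wn)
    if cfg.amplitude_cv > 0:
        sigma = float(np.sqrt(np.log1p(cfg.amplitude_cv**2)))
    else:
        sigma = 0.0
    for band in bands:
        center = band.center + rng.normal(0.0, cfg.center_jitter_sd)
        if sigma > 0:
            amp = band.amplitude * rng.lognormal(-0.5 * sigma**2, sigma)
        else:
            amp = band.amplitude
        y += band.evaluate(wn, center=center, amplitude=amp)
    if cfg.baseline_scale > 0:
        u = (wn - wn.mean()) / ((wn[-1] - wn[0]) / 2.0)
        coeffs = rng.normal(0.0, cfg.baseline_scale, cfg.baseline_degree + 1)
        y += np.polyval(coeffs, u)
    if cfg.noise_sd > 0:
        y += rng.normal(0.0, cfg.noise_sd, wn.size)
    meta = SampleMeta(
        sample_id=sample_id or f"{SPECIES_ABBREV.get(tmpl.species, 'sp')}_sample",
        species=tmpl.species,
        forest_type=context["forest_type"],
        site=context["site"],
        host_tree=context.get("host_tree", "unknown"),
    )
    return Spectrum(grid, y, meta)


def generate_dataset(
    cfg: GeneratorConfig = GeneratorConfig(),
    templates: Mapping[str, SpeciesTemplate] | None = None,
    grid: WavenumberGrid = CANONICAL_GRID,
) -> SpectralDataset:
    """Generate the full labelled dataset for a composition table.

    Sample ``i`` (in composition order) always draws from RNG substream
    ``(seed, i)``, so adding or removing composition entries does not
    change the other samples' spectra.
    """
    templates = templates or builtin_templates()
    spectra: list[Spectrum] = []
    index = 0
    for entry in cfg.composition:
        tmpl = templates[entry.species]
        abbrev = SPECIES_ABBREV.get(entry.species, entry.species[:2])
        for _ in range(entry.count):
            sid = (
                f"{abbrev}_{entry.site}_{entry.forest_type}_"
                f"{entry.host_tree}_{index:03d}"
            )
            spectra.append(
                generate_spectrum(
                    tmpl,
                    {
                        "site": entry.site,
                        "forest_type": entry.forest_type,
                        "host_tree": entry.host_tree,
                    },
                    cfg,
                    _sample_rng(cfg.seed, index),
                    grid=grid,
                    sample_id=sid,
                )
            )
            index += 1
    return SpectralDataset(spectra, grid)


#: Cellulose bands used as the positive control for the contamination screen.
CELLULOSE_BANDS: tuple[BandTemplate, ...] = (
    BandTemplate(1641.0, 12.0, 0.8, "lorentzian", "cellulose"),
    BandTemplate(1427.0, 12.0, 0.8, "lorentzian", "cellulose"),
    BandTemplate(1335.0, 12.0, 0.8, "lorentzian", "cellulose"),
    BandTemplate(1160.0, 12.0, 0.8, "lorentzian", "cellulose"),
)


def generate_cellulose_spectrum(
    cfg: GeneratorConfig = GeneratorConfig(),
    grid: WavenumberGrid = CANONICAL_GRID,
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """Synthetic plant-cellulose spectrum (contamination positive control)."""
    rng = rng or _sample_rng(cfg.seed, 10**6)
    wn = grid.wavenumbers
    y = np.zeros_like(wn)
    for band in CELLULOSE_BANDS:
        center = band.center + rng.normal(0.0, cfg.center_jitter_sd)
        y += band.evaluate(wn, center=center)
    if cfg.noise_sd > 0:
        y += rng.normal(0.0, cfg.noise_sd, wn.size)
    return Spectrum(grid, y, SampleMeta(sample_id="cellulose_control"))
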