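"""Second-derivative preprocessing and diagnostic-window feature extraction.

The feature vector fed to hierarchical clustering is the Savitzky-Golay
second derivative (17 points, cubic) of the absorbance trace, restricted to
the diagnostic wavenumber windows, concatenated in descending-wavenumber
order, then mean-centered and scaled to unit Euclidean norm.  The second
derivative removes additive baselines and sharpens overlapped bands; the
vector normalization removes the per-sample intensity scale set by contact
pressure on the ATR crystal.

Two named window sets are provided:

``hca``
    3000–2800 and 1700–600 cm⁻¹ — the region actually clustered.
``functional5``
    The five functional-group windows: (I) fatty acids 3000–2800, (II)
    amide I 1700–1600, (III) amide II+III 1575–1300, (IV) polysaccharides
    1200–900, (V) fingerprint 900–600 cm⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .io import Spectrum, SpectralDataset

__all__ = [
    "SpectralWindow",
    "PreprocessConfig",
    "FeatureVector",
    "WINDOW_SETS",
    "second_derivative",
    "vector_normalize",
    "extract_features",
    "extract_dataset_features",
]


@dataclass(frozen=True)
class SpectralWindow:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"window {self.name!r}: lo must be < hi")


WINDOW_SETS: dict[str, tuple[SpectralWindow, ...]] = {
    "hca": (
        SpectralWindow("fatty_acids", 2800.0, 3000.0),
        SpectralWindow("main", 600.0, 1700.0),
    ),
    "functional5": (
        SpectralWindow("I_fatty_acids", 2800.0, 3000.0),
        SpectralWindow("II_amide_I", 1600.0, 1700.0),
        SpectralWindow("III_amide_II_III", 1300.0, 1575.0),
        SpectralWindow("IV_polysaccharides", 900.0, 1200.0),
        SpectralWindow("V_fingerprint", 600.0, 900.0),
    ),
}


@dataclass(frozen=True)
class PreprocessConfig:
    sg_points: int = 17
    sg_polyorder: int = 3
    derivative_order: int = 2
    normalize: str = "vector"  # "vector" | "none"
    windows: tuple[SpectralWindow, ...] = WINDOW_SETS["hca"]
    derivative_wrt: str = "wavenumber"  # "wavenumber" | "index"

    def __post_init__(self) -> None:
        if self.sg_points % 2 == 0 or self.sg_points <= self.sg_polyorder:
            raise ValueError("sg_points must be odd and > sg_polyorder")
        if self.derivative_order > self.sg_polyorder:
            raise ValueError("derivative_order must be <= sg_polyorder")
        if self.normalize not in ("vector", "none"):
            raise ValueError(f"unknown normalize mode {self.normalize!r}")
        if self.derivative_wrt not in ("wavenumber", "index"):
            raise ValueError(f"unknown derivative_wrt {self.derivative_wrt!r}")

    @classmethod
    def with_windows(cls, name: str, **kwargs) -> "PreprocessConfig":
        if name not in WINDOW_SETS:
            raise ValueError(f"unknown window set {name!r}; have {sorted(WINDOW_SETS)}")
        return cls(windows=WINDOW_SETS[name], **kwargs)


@dataclass
class FeatureVector:
    sample_id: str
    values: np.ndarray
    support: np.ndarray  # wavenumbers, descending-window concatenation order

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.support = np.asarray(self.support, dtype=float)
        if self.values.shape != self.support.shape:
            raise ValueError("values and support must have equal length")


def second_derivative(s: Spectrum, cfg: PreprocessConfig = PreprocessConfig()) -> Spectrum:
    """Savitzky-Golay second derivative of an absorbance spectrum.

    With ``derivative_wrt="wavenumber"`` the values are per cm⁻², i.e.
    independent of the grid step.  Edge points use the one-sided polynomial
    fit (scipy's ``mode="interp"``), so no data are fabricated beyond the
    measured range.
    """
    if s.grid.n_points < cfg.sg_points:
        raise ValueError(
            f"spectrum has {s.grid.n_points} points < sg_points={cfg.sg_points}"
        )
    delta = s.grid.step if cfg.derivative_wrt == "wavenumber" else 1.0
    d2 = savgol_filter(
        s.absorbance,
        window_length=cfg.sg_points,
        polyorder=cfg.sg_polyorder,
        deriv=cfg.derivative_order,
        delta=delta,
        mode="interp",
    )
    return s.with_absorbance(d2)


def vector_normalize(v: np.ndarray) -> np.ndarray:
    """Mean-center and scale to unit Euclidean norm.

    Invariant under affine transformations v -> a·v + b (a > 0); raises on
    constant input (zero norm after centering).
    """
    v = np.asarray(v, dtype=float)
    centered = v - v.mean()
    norm = np.linalg.norm(centered)
    if norm == 0.0:
        raise ValueError("cannot vector-normalize a constant vector")
    return centered / norm


def extract_features(s: Spectrum, cfg: PreprocessConfig = PreprocessConfig()) -> FeatureVector:
    """Derivative → window slicing → concatenation → vector normalization.

    Windows are concatenated in descending-wavenumber order with inclusive
    endpoints; within each window, values follow descending wavenumber too,
    matching the conventional right-to-left FTIR display.
    """
    d2 = second_derivative(s, cfg)
    wn = s.wavenumbers
    pieces: list[np.ndarray] = []
    supports: list[np.ndarray] = []
    for window in sorted(cfg.windows, key=lambda w: -w.hi):
        try:
            sl = s.grid.slice(window.lo, window.hi)
        except ValueError as exc:
            raise ValueError(f"window {window.name!r}: {exc}") from exc
        pieces.append(d2.absorbance[sl][::-1])
        supports.append(wn[sl][::-1])
    values = np.concatenate(pieces)
    support = np.concatenate(supports)
    if cfg.normalize == "vector":
        values = vector_normalize(values)
    return FeatureVector(sample_id=s.meta.sample_id, values=values, support=support)


def extract_dataset_features(
    ds: SpectralDataset, cfg: PreprocessConfig = PreprocessConfig()
) -> list[FeatureVector]:
    """Pure per-sample map of :func:`extract_features` over a dataset."""
    return [extract_features(s, cfg) for s in ds]
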