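"""Direct classical least squares (DCLS) spectral demultiplexing.

Each SERS nanoparticle flavor emits a narrow fingerprint spectrum under a
single 785-nm excitation.  A raw tissue spectrum is modelled as a
non-negative linear mixture of the flavor reference spectra plus the
unstained-tissue background; the fitted weights are converted to molar
concentrations through a calibration measurement of the equimolar stock
mixture (150 pM per flavor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "RamanSpectrum",
    "ReferenceLibrary",
    "CalibrationFactor",
    "UnmixResult",
    "synth_reference",
    "dcls_unmix",
    "calibrate",
    "STOCK_CONCENTRATION_PM",
]

#: per-flavor concentration of the calibration stock mixture (pM)
STOCK_CONCENTRATION_PM = 150.0

#: condition number above which the reference library is rejected
CONDITION_LIMIT = 1e8

MIN_CHANNELS = 16


@dataclass
class RamanSpectrum:
    """Intensity versus wavenumber on a fixed channel grid."""

    channels: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.channels.shape != self.intensities.shape or self.channels.ndim != 1:
            raise ValueError("channels and intensities must be equal-length 1-D arrays")
        if len(self.channels) < MIN_CHANNELS:
            raise ValueError(f"need at least {MIN_CHANNELS} channels")
        if np.any(np.diff(self.channels) <= 0):
            raise ValueError("channels must be strictly increasing")

    def __len__(self) -> int:
        return len(self.channels)


def _same_grid(a: np.ndarray, b: np.ndarray) -> bool:
    return a.shape == b.shape and np.allclose(a, b, rtol=0, atol=1e-9)


@dataclass
class ReferenceLibrary:
    """Named flavor fingerprints plus the unstained-tissue background.

    All spectra must share one channel grid; the flavor spectra must be
    linearly independent (the library is rejected if the reference matrix
    condition number exceeds ``CONDITION_LIMIT``).
    """

    flavor_spectra: dict[str, RamanSpectrum]
    background: RamanSpectrum

    def __post_init__(self) -> None:
        if not self.flavor_spectra:
            raise ValueError("library needs at least one flavor spectrum")
        grid = self.background.channels
        for name, spec in self.flavor_spectra.items():
            if not _same_grid(grid, spec.channels):
                raise ValueError(f"flavor {name!r} is not on the library channel grid")
        cond = np.linalg.cond(self.reference_matrix())
        if not np.isfinite(cond) or cond > CONDITION_LIMIT:
            raise ValueError(
                f"reference library is ill-conditioned (cond={cond:.3g}); "
                f"collinear flavors: {self._most_collinear()}"
            )

    @property
    def flavor_names(self) -> list[str]:
        return list(self.flavor_spectra)

    @property
    def channels(self) -> np.ndarray:
        return self.background.channels

    def reference_matrix(self) -> np.ndarray:
        """Columns are the flavor spectra (background excluded)."""
        return np.column_stack(
            [self.flavor_spectra[n].intensities for n in self.flavor_names]
        )

    def _most_collinear(self) -> tuple[str, str] | str:
        names = self.flavor_names
        if len(names) < 2:
            return names[0]
        M = self.reference_matrix()
        norms = np.linalg.norm(M, axis=0)
        norms[norms == 0] = 1.0
        C = np.abs((M / norms).T @ (M / norms))
        np.fill_diagonal(C, 0.0)
        i, j = np.unravel_index(np.argmax(C), C.shape)
        return (names[i], names[j])


@dataclass(frozen=True)
class CalibrationFactor:
    """pM of nanoparticle per unit demultiplexed weight for one flavor."""

    scale: float
    source: str = "stock"

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("calibration scale must be > 0")


@dataclass
class UnmixResult:
    weights: dict[str, float]
    background_weight: float
    residual_norm: float

    def as_vector(self, names: list[str]) -> np.ndarray:
        return np.array([self.weights[n] for n in names])


def synth_reference(
    peaks: list[tuple[float, float, float]], channels: np.ndarray
) -> RamanSpectrum:
    """Render a synthetic fingerprint as a sum of Lorentzian lines.

    ``peaks`` is a list of ``(center cm⁻¹, half-width cm⁻¹, height)``.
    Deterministic; a peak centred outside the channel range is still
    rendered (its tail may enter the window) but triggers a warning.
    """
    channels = np.asarray(channels, dtype=float)
    intensities = np.zeros_like(channels)
    for center, width, height in peaks:
        if not width > 0:
            raise ValueError("peak widths must be > 0")
        if not channels[0] <= center <= channels[-1]:
            warnings.warn(
                f"peak center {center} cm^-1 outside channel range "
                f"[{channels[0]}, {channels[-1]}]",
                stacklevel=2,
            )
        intensities += height / (1.0 + ((channels - center) / width) ** 2)
    return RamanSpectrum(channels, intensities)


def dcls_unmix(
    spectrum: RamanSpectrum,
    library: ReferenceLibrary,
    nonneg: bool = True,
    subtract_background: bool = False,
    baseline_order: int | None = None,
) -> UnmixResult:
    """Least-squares decomposition of a spectrum against the library.

    The composite spectrum is modelled as ``Σ wᵢ·refᵢ + w_b·background``.
    By default the background is co-fit as an extra component with a free
    weight; ``subtract_background=True`` instead subtracts it (unit weight)
    before unmixing.  ``baseline_order`` (0, 1 or 2) appends polynomial
    baseline columns.  With ``nonneg`` the flavor weights are constrained
    to be non-negative.
    """
    if not _same_grid(spectrum.channels, library.channels):
        raise ValueError("spectrum is not on the library channel grid")
    names = library.flavor_names
    y = spectrum.intensities.astype(float)
    columns = [library.reference_matrix()]
    extra_labels: list[str] = []
    if subtract_background:
        y = y - library.background.intensities
    else:
        columns.append(library.background.intensities[:, None])
        extra_labels.append("background")
    if baseline_order is not None:
        if baseline_order not in (0, 1, 2):
            raise ValueError("baseline_order must be 0, 1 or 2")
        x = np.linspace(-1, 1, len(y))
        columns.append(np.column_stack([x**p for p in range(baseline_order + 1)]))
        extra_labels.extend(f"baseline{p}" for p in range(baseline_order + 1))
    M = np.hstack(columns)
    if nonneg:
        coef, _ = nnls(M, y)
    else:
        coef, *_ = np.linalg.lstsq(M, y, rcond=None)
    residual = float(np.linalg.norm(M @ coef - y))
    weights = {n: float(c) for n, c in zip(names, coef[: len(names)])}
    background_weight = (
        1.0 if subtract_background else float(coef[len(names)])
    )
    return UnmixResult(weights, background_weight, residual)


def calibrate(
    weights: dict[str, float],
    stock_weights: dict[str, float],
    stock_concentration: float = STOCK_CONCENTRATION_PM,
) -> dict[str, float]:
    """Convert demultiplexed weights to concentrations (pM).

    ``concentrationᵢ = weightᵢ · stock_concentration / stock_weightᵢ``,
    where ``stock_weights`` come from unmixing the calibration droplet of
    the equimolar stock mixture.
    """
    out: dict[str, float] = {}
    for name, w in weights.items():
        sw = stock_weights.get(name)
        if sw is None or not sw > 0:
            raise ValueError(f"unusable stock weight for flavor {name!r}: {sw}")
        factor = CalibrationFactor(scale=stock_concentration / sw, source="stock")
        out[name] = w * factor.scale
    return out
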