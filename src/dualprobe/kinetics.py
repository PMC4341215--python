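"""Forward compartment models for dual-probe rinse kinetics.

Topically stained tissue is modelled as a linear three-compartment system:
free probe ``C_free`` exchanges with a specifically bound pool ``C_bound``
(association ``k3``, dissociation ``k4``) and with a nonspecifically bound
pool ``C_ns`` (``k5``, ``k6``).  During serial rinsing the free pool is
additionally cleared at a first-order washout rate ``F``.  The binding
potential ``BP = k3/k4`` is the equilibrium ratio of specifically bound to
free probe and is proportional to available receptor concentration.

Two model variants are supported: ``"DPM"`` (dual-probe model, no
nonspecific compartment) and ``"DPM-NS"`` (with nonspecific binding).  An
untargeted (isotype-control) probe is the same system with ``k3 = k4 = 0``;
it shares ``F``, ``k5`` and ``k6`` with its paired targeted probe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import expm

__all__ = [
    "RateConstants",
    "AcquisitionSchedule",
    "CompartmentState",
    "ConcentrationCurve",
    "DualProbeMeasurement",
    "build_generator",
    "solve_compartments",
    "simulate_stain_phase",
    "simulate_dual_probe",
    "VARIANTS",
    "PROBES",
]

VARIANTS = ("DPM", "DPM-NS")
PROBES = ("targeted", "untargeted")

#: concentration of each probe in the staining mixture (pM)
DEFAULT_APPLIED_PM = 150.0


def _check_rate(name: str, value: float) -> None:
    # NaN marks a rate an estimator did not touch; only finite values are range-checked
    if math.isfinite(value) and value < 0:
        raise ValueError(f"rate constant {name} must be >= 0, got {value}")


@dataclass(frozen=True)
class RateConstants:
    """Kinetic parameters of the dual-probe compartment model.

    All rates are first-order and carry units of min⁻¹.  ``F`` is the rinse
    washout rate of the free pool; ``k3``/``k4`` govern specific binding and
    ``k5``/``k6`` nonspecific binding.  ``NaN`` entries denote "not
    applicable" (used in fit reports for rates an estimator does not touch).
    """

    F: float
    k3: float = 0.0
    k4: float = 0.0
    k5: float = 0.0
    k6: float = 0.0

    def __post_init__(self) -> None:
        for name in ("F", "k3", "k4", "k5", "k6"):
            _check_rate(name, getattr(self, name))

    @property
    def binding_potential(self) -> float:
        """``k3/k4``, defined only for a positive dissociation rate."""
        if not self.k4 > 0:
            raise ValueError("binding potential requires k4 > 0")
        return self.k3 / self.k4

    def as_untargeted(self) -> "RateConstants":
        """Rates of the paired isotype-control probe (``k3 = k4 = 0``)."""
        return replace(self, k3=0.0, k4=0.0)


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Stain-and-rinse measurement schedule.

    ``t = 0`` is the end of staining; measurement ``i`` (0-based, ``i = 0``
    the pre-rinse reading) is taken at ``t = i * rinse_interval`` minutes.
    """

    stain_duration: float = 10.0
    rinse_interval: float = 0.5
    n_rinses: int = 10
    include_pre_rinse: bool = True

    def __post_init__(self) -> None:
        if not self.stain_duration > 0:
            raise ValueError("stain_duration must be > 0")
        if not self.rinse_interval > 0:
            raise ValueError("rinse_interval must be > 0")
        if self.n_rinses < 2:
            raise ValueError("n_rinses must be >= 2")

    @property
    def n_measurements(self) -> int:
        return self.n_rinses + (1 if self.include_pre_rinse else 0)

    def measurement_times(self) -> np.ndarray:
        start = 0 if self.include_pre_rinse else 1
        idx = np.arange(start, self.n_rinses + 1, dtype=float)
        return idx * self.rinse_interval


@dataclass(frozen=True)
class CompartmentState:
    """Probe concentrations (pM) in the free, bound and nonspecific pools."""

    free: float
    bound: float = 0.0
    ns: float = 0.0

    @property
    def total(self) -> float:
        return self.free + self.bound + self.ns

    def as_array(self) -> np.ndarray:
        return np.array([self.free, self.bound, self.ns], dtype=float)


@dataclass
class ConcentrationCurve:
    """Total probe concentration versus time for one probe on one sample."""

    probe_label: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.probe_label not in PROBES:
            raise ValueError(f"probe_label must be one of {PROBES}")
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class DualProbeMeasurement:
    """Paired targeted/untargeted curves on a shared rinse schedule."""

    sample_id: str
    tissue_label: str
    targeted: ConcentrationCurve
    untargeted: ConcentrationCurve

    def __post_init__(self) -> None:
        if self.targeted.probe_label != "targeted":
            raise ValueError("targeted curve must be labelled 'targeted'")
        if self.untargeted.probe_label != "untargeted":
            raise ValueError("untargeted curve must be labelled 'untargeted'")
        if not np.array_equal(self.targeted.times, self.untargeted.times):
            raise ValueError("paired curves must share identical time points")

    @property
    def times(self) -> np.ndarray:
        return self.targeted.times


def _effective_rates(rates: RateConstants, variant: str, probe: str) -> tuple[float, float, float, float, float]:
    if variant not in VARIANTS:
        raise ValueError(f"unknown model variant {variant!r}; expected one of {VARIANTS}")
    if probe not in PROBES:
        raise ValueError(f"unknown probe {probe!r}; expected one of {PROBES}")
    k3, k4 = (rates.k3, rates.k4) if probe == "targeted" else (0.0, 0.0)
    k5, k6 = (rates.k5, rates.k6) if variant == "DPM-NS" else (0.0, 0.0)
    return rates.F, k3, k4, k5, k6


def build_generator(
    rates: RateConstants,
    variant: str = "DPM-NS",
    probe: str = "targeted",
    washout_active: bool = True,
) -> np.ndarray:
    """Linear ODE generator ``A`` with ``dC/dt = A @ C`` over (free, bound, ns).

    Binding exchange conserves total probe (sub-block columns sum to zero);
    the only sink is the washout term ``-F`` on the free diagonal, present
    when ``washout_active``.
    """
    F, k3, k4, k5, k6 = _effective_rates(rates, variant, probe)
    w = F if washout_active else 0.0
    return np.array(
        [
            [-(w + k3 + k5), k4, k6],
            [k3, -k4, 0.0],
            [k5, 0.0, -k6],
        ]
    )


# eigenvalue-gap threshold below which the eigenbasis is unreliable
_DEGENERACY_TOL = 1e-10


def _propagate(A: np.ndarray, x0: np.ndarray, times: np.ndarray) -> np.ndarray:
    """States at ``times`` for ``dx/dt = A x``; rows are time points.

    Uses the eigen-decomposition of ``A`` (exact for this linear system);
    falls back to scaling-and-squaring ``expm`` per time point when
    eigenvalues are near-degenerate or leave the real axis.
    """
    times = np.asarray(times, dtype=float)
    if not _eig_usable(A):
        return np.stack([expm(A * t) @ x0 for t in times])
    w, V = np.linalg.eig(A)
    w, V = w.real, V.real
    c = np.linalg.solve(V, x0)
    return (np.exp(np.outer(times, w)) * c) @ V.T


def _eig_usable(A: np.ndarray) -> bool:
    """Whether the eigen-decomposition of ``A`` is safe for propagation.

    Rejects near-degenerate or complex spectra and — because LAPACK can
    return inaccurate eigenvectors for badly scaled compartment matrices —
    also verifies the reconstruction residual ``A V - V diag(w)``.
    """
    w, V = np.linalg.eig(A)
    scale = max(1.0, np.abs(w).max())
    gaps = np.abs(w[:, None] - w[None, :])[~np.eye(len(w), dtype=bool)]
    if gaps.size and gaps.min() < _DEGENERACY_TOL * scale:
        return False
    if np.abs(w.imag).max() > 1e-12 * scale:
        return False
    resid = np.abs(A @ V - V * w).max()
    return resid <= 1e-10 * max(1.0, np.abs(A).max())


def solve_compartments(
    initial: CompartmentState,
    rates: RateConstants,
    times: np.ndarray,
    variant: str = "DPM-NS",
    probe: str = "targeted",
    washout_active: bool = True,
) -> list[CompartmentState]:
    """Exact solution of the compartment system at the requested times."""
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if times.size > 1 and np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    A = build_generator(rates, variant, probe, washout_active)
    states = _propagate(A, initial.as_array(), times)
    return [CompartmentState(*row) for row in states]


def simulate_stain_phase(
    applied_concentration: float,
    rates: RateConstants,
    stain_duration: float = 10.0,
    variant: str = "DPM-NS",
    probe: str = "targeted",
) -> CompartmentState:
    """Compartment state at the end of staining (no washout; closed system).

    The stain starts with all probe free, ``(applied_concentration, 0, 0)``;
    total concentration is conserved throughout the stain phase.
    """
    if not applied_concentration > 0:
        raise ValueError("applied_concentration must be > 0")
    (state,) = solve_compartments(
        CompartmentState(free=applied_concentration),
        rates,
        np.array([stain_duration]),
        variant,
        probe,
        washout_active=False,
    )
    return state


def _clean_totals(
    rates: RateConstants,
    schedule: AcquisitionSchedule,
    probe: str,
    variant: str,
    applied_concentration: float,
) -> np.ndarray:
    """Noiseless total-concentration curve over the measurement schedule."""
    stain = simulate_stain_phase(
        applied_concentration, rates, schedule.stain_duration, variant, probe
    )
    A = build_generator(rates, variant, probe, washout_active=True)
    states = _propagate(A, stain.as_array(), schedule.measurement_times())
    return states.sum(axis=1)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_dual_probe(
    rates_targeted: RateConstants,
    schedule: AcquisitionSchedule = AcquisitionSchedule(),
    noise_percent: float = 0.48,
    seed=None,
    applied_concentration: float = DEFAULT_APPLIED_PM,
    variant: str = "DPM-NS",
    sample_id: str = "sim",
    tissue_label: str = "simulated",
) -> DualProbeMeasurement:
    """Simulate a paired targeted/untargeted acquisition.

    The untargeted probe is assumed ideal: it shares ``F``, ``k5`` and
    ``k6`` with the targeted probe and has ``k3 = k4 = 0``.  Both probes
    start from their own stain-phase state.  Gaussian noise with standard
    deviation ``(noise_percent/100) * RMS(clean curve)`` is added i.i.d.
    per point; negative noisy values are retained (fitting tolerates them).

    ``seed`` may be an int, a :class:`numpy.random.SeedSequence` or a
    :class:`numpy.random.Generator`; identical seeds give identical output.
    """
    if noise_percent < 0:
        raise ValueError("noise_percent must be >= 0")
    rng = _as_rng(seed)
    times = schedule.measurement_times()
    curves: dict[str, ConcentrationCurve] = {}
    for probe in PROBES:
        rates = rates_targeted if probe == "targeted" else rates_targeted.as_untargeted()
        clean = _clean_totals(rates, schedule, probe, variant, applied_concentration)
        sigma = (noise_percent / 100.0) * float(np.sqrt(np.mean(clean**2)))
        values = clean + rng.normal(0.0, sigma, size=clean.shape) if sigma > 0 else clean
        curves[probe] = ConcentrationCurve(probe, times.copy(), values)
    return DualProbeMeasurement(
        sample_id=sample_id,
        tissue_label=tissue_label,
        targeted=curves["targeted"],
        untargeted=curves["untargeted"],
    )
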