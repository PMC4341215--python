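"""Binding-potential estimators for dual-probe rinse curves.

Three estimators are provided:

``Ratio``
    ``(targeted - untargeted) / untargeted`` concentration at a single rinse
    step (by default the final one).  Fast, but it treats nonspecifically
    bound probe as free and therefore underestimates BP when nonspecific
    binding is present.

``DPM``
    Dual-probe model without nonspecific binding.  A two-step fit: the
    untargeted curve is fit with a monoexponential ``A·exp(-F·t)`` to
    estimate the rinse rate ``F``; ``F`` is then fixed while the targeted
    curve is fit with the free+bound two-compartment model to estimate
    ``k3``, ``k4`` and ``BP = k3/k4``.

``DPM-NS``
    Dual-probe model with a nonspecific compartment.  The untargeted curve
    yields ``F``, ``k5`` and ``k6``; these are fixed while the targeted
    curve is fit with the full three-compartment model for ``k3``, ``k4``.

All fits are separable: rate constants are searched nonlinearly (bounded
least squares from several deterministic starts) while the linear amplitude
coefficients are solved per candidate — by non-negative least squares for
the DPM fits and by a randomized-column Kaczmarz iteration with Tikhonov
regularization for the DPM-NS fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm, qr, solve_triangular
from scipy.optimize import least_squares, nnls

from .kinetics import (
    ConcentrationCurve,
    DualProbeMeasurement,
    RateConstants,
    build_generator,
)

__all__ = [
    "SolverOptions",
    "KaczmarzSolution",
    "FitResult",
    "kaczmarz_tikhonov_solve",
    "bp_ratio",
    "fit_untargeted_dpm",
    "fit_targeted_dpm",
    "fit_untargeted_dpmns",
    "fit_targeted_dpmns",
    "estimate_bp",
]

#: upper box bound on all searched rate constants (min^-1)
RATE_UPPER = 20.0
#: lower box bound on k4, preventing unbounded BP
K4_FLOOR = 1e-6
#: reference threshold below which the ratio estimator refuses to divide (pM)
RATIO_EPS = 1e-6
#: deterministic multi-start grid for the nonlinear searches (min^-1)
N_STARTS = 8
_START_GRID = np.logspace(np.log10(0.01), np.log10(1.0), N_STARTS)


@dataclass(frozen=True)
class SolverOptions:
    """Options for :func:`kaczmarz_tikhonov_solve`.

    ``tikhonov_lambda=None`` selects the default
    ``1e-4 * trace(BᵀB) / n_components`` for the basis at hand.
    """

    tikhonov_lambda: float | None = None
    max_sweeps: int = 400
    tolerance: float = 1e-12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tikhonov_lambda is not None and self.tikhonov_lambda < 0:
            raise ValueError("tikhonov_lambda must be >= 0")
        if self.max_sweeps < 1:
            raise ValueError("max_sweeps must be >= 1")
        if not self.tolerance > 0:
            raise ValueError("tolerance must be > 0")


@dataclass
class KaczmarzSolution:
    coefficients: np.ndarray
    converged: bool
    n_sweeps: int
    residual_norm: float


@dataclass
class FitResult:
    """Outcome of one estimator on one sample.

    ``rates`` carries ``NaN`` for parameters the estimator does not
    estimate; ``bp`` is ``NaN`` for untargeted-curve fits (they estimate
    rinse/nonspecific rates only).
    """

    estimator: str
    rates: RateConstants
    amplitudes: np.ndarray
    bp: float
    residual_norm: float
    n_points: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "estimator": self.estimator,
            "rates": {
                k: getattr(self.rates, k) for k in ("F", "k3", "k4", "k5", "k6")
            },
            "amplitudes": [float(a) for a in np.atleast_1d(self.amplitudes)],
            "bp": float(self.bp),
            "residual_norm": float(self.residual_norm),
            "n_points": int(self.n_points),
            "converged": bool(self.converged),
        }


def _default_lambda(basis: np.ndarray) -> float:
    return 1e-4 * float(np.trace(basis.T @ basis)) / basis.shape[1]


def kaczmarz_tikhonov_solve(
    basis: np.ndarray,
    observations: np.ndarray,
    opts: SolverOptions = SolverOptions(),
) -> KaczmarzSolution:
    """Ridge-regularized linear solve by randomized column Kaczmarz sweeps.

    Approximately minimizes ``||basis @ c - obs||^2 + lambda * ||c||^2`` by
    exact coordinate updates in a column order re-randomized each sweep
    (seeded, hence deterministic).  Each update minimizes the regularized
    objective along its coordinate, so the objective is non-increasing
    sweep to sweep; the iterates converge to the closed-form solution
    ``(BᵀB + λI)⁻¹ Bᵀ y``.
    """
    B = np.atleast_2d(np.asarray(basis, dtype=float))
    y = np.asarray(observations, dtype=float).ravel()
    if B.shape[0] != y.shape[0]:
        raise ValueError("basis and observations are not conformable")
    lam = opts.tikhonov_lambda if opts.tikhonov_lambda is not None else _default_lambda(B)
    m, n = B.shape
    col_sq = np.einsum("ij,ij->j", B, B)
    c = np.zeros(n)
    r = y.copy()
    rng = np.random.default_rng(opts.seed)
    converged = False
    sweep = 0
    for sweep in range(1, opts.max_sweeps + 1):
        max_step = 0.0
        for j in rng.permutation(n):
            denom = col_sq[j] + lam
            if denom <= 0.0:
                continue
            delta = (B[:, j] @ r - lam * c[j]) / denom
            c[j] += delta
            r -= delta * B[:, j]
            max_step = max(max_step, abs(delta))
        if max_step <= opts.tolerance * max(1.0, float(np.abs(c).max())):
            converged = True
            break
    return KaczmarzSolution(c, converged, sweep, float(np.linalg.norm(r)))


def _ridge_via_kaczmarz(
    basis: np.ndarray, y: np.ndarray, opts: SolverOptions
) -> tuple[np.ndarray, bool]:
    """Amplitude solve used by the DPM-NS fits.

    The exponential-basis columns can be nearly collinear (slow bound and
    nonspecific responses look alike over a short rinse window), which
    stalls a raw column-action iteration.  The basis is therefore
    orthonormalized by pivoted QR first; the Kaczmarz sweeps run on the
    well-conditioned factor (where they converge in a few sweeps) and the
    coefficients are mapped back.  Rank-deficient columns (e.g. an empty
    bound compartment when ``k3 = 0``) receive zero coefficients.
    """
    m, n = basis.shape
    Q, R, piv = qr(basis, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(m, n) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    c = np.zeros(n)
    if rank == 0:
        return c, True
    if opts.tikhonov_lambda is None:
        # On the orthonormal factor the penalty acts as uniform shrinkage
        # only (conditioning is handled by the QR), so default to a tiny
        # weight: the shrinkage bias must sit far below measurement noise
        # and below the residuals compared in nested-model F-tests.
        from dataclasses import replace as _dc_replace

        opts = _dc_replace(opts, tikhonov_lambda=1e-8)
    sol = kaczmarz_tikhonov_solve(Q[:, :rank], y, opts)
    c_r = solve_triangular(R[:rank, :rank], sol.coefficients)
    c[piv[:rank]] = c_r
    return c, sol.converged


def bp_ratio(
    measurement: DualProbeMeasurement,
    rinse_index: int | None = None,
    eps: float = RATIO_EPS,
) -> float:
    """Ratiometric BP estimate ``(T - U)/U`` at one rinse step.

    ``rinse_index`` indexes the measurement points (0 = pre-rinse when
    present); the default is the final rinse.  May be negative under noise
    when the targeted reading falls below the untargeted one.
    """
    n = len(measurement.targeted)
    idx = n - 1 if rinse_index is None else rinse_index
    if not -n <= idx < n:
        raise IndexError(f"rinse_index {rinse_index} outside curve of length {n}")
    t = float(measurement.targeted.values[idx])
    u = float(measurement.untargeted.values[idx])
    if u <= eps:
        raise ZeroDivisionError(
            f"untargeted reference {u:.3g} pM at index {idx} is <= {eps:.3g} pM"
        )
    return (t - u) / u


def _active_indices(variant: str, probe: str) -> list[int]:
    idx = [0]
    if probe == "targeted":
        idx.append(1)
    if variant == "DPM-NS":
        idx.append(2)
    return idx


def _reduced_generator(
    rates: RateConstants, variant: str, probe: str, washout_active: bool
) -> np.ndarray:
    """Generator restricted to the compartments the variant/probe uses."""
    A = build_generator(rates, variant, probe, washout_active)
    idx = _active_indices(variant, probe)
    return A[np.ix_(idx, idx)]


def _total_response_basis(A: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Columns are total-signal responses to a unit initial load per compartment."""
    n = A.shape[0]
    basis = _propagate_totals(A, np.eye(n), times)
    return basis


def _propagate_totals(A: np.ndarray, X0: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Total signal 1ᵀ·exp(A t)·x0 for each column x0 of X0, rows = times."""
    from .kinetics import _eig_usable

    if not _eig_usable(A):
        rows = [np.ones(A.shape[0]) @ expm(A * t) @ X0 for t in times]
        return np.atleast_2d(np.stack(rows))
    w, V = np.linalg.eig(A)
    w, V = w.real, V.real
    u = V.sum(axis=0)  # 1ᵀ V
    C = np.linalg.solve(V, X0)  # eigen coefficients per column
    return (np.exp(np.outer(times, w)) * u) @ C


def _validate_curve(curve: ConcentrationCurve, probe: str, min_points: int) -> None:
    if curve.probe_label != probe:
        raise ValueError(f"expected a {probe} curve, got {curve.probe_label!r}")
    if len(curve) < min_points:
        raise ValueError(f"need at least {min_points} points, got {len(curve)}")
    if np.allclose(curve.values, 0.0):
        raise ValueError("degenerate all-zero concentration curve")


def _multi_starts(n_params: int) -> np.ndarray:
    """Deterministic start vectors spread over the log-spaced rate grid."""
    starts = np.empty((N_STARTS, n_params))
    for i in range(N_STARTS):
        for j in range(n_params):
            starts[i, j] = _START_GRID[(i + 3 * j) % N_STARTS]
    return starts


def _search(
    residual_fn, bounds_lo, bounds_hi, starts, tie_key=None
) -> tuple[np.ndarray, float, bool]:
    """Bounded least-squares from each start; best residual wins.

    Near-ties (costs within 1e-9 relative) are broken by ``tie_key``
    (smaller wins; the targeted fits pass ``BP = k3/k4``).
    """
    runs = []
    for x0 in starts:
        x0 = np.clip(x0, bounds_lo, bounds_hi)
        sol = least_squares(
            residual_fn,
            x0,
            bounds=(bounds_lo, bounds_hi),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=200,
        )
        runs.append(sol)
    best_cost = min(s.cost for s in runs)
    tied = [s for s in runs if s.cost <= best_cost * (1 + 1e-9) + 1e-300]
    if tie_key is not None and len(tied) > 1:
        best = min(tied, key=lambda s: tie_key(s.x))
    else:
        best = min(tied, key=lambda s: s.cost)
    return best.x, best.cost, best.success


def fit_untargeted_dpm(curve: ConcentrationCurve) -> FitResult:
    """Fit ``A·exp(-F·t)`` to an untargeted curve to estimate the rinse rate.

    Separable non-negative fit: for each candidate ``F`` the amplitude is
    the one-column non-negative least-squares solution in closed form.
    """
    _validate_curve(curve, "untargeted", 3)
    t, y = curve.times, curve.values

    def amp(F: float) -> tuple[float, np.ndarray]:
        e = np.exp(-F * t)
        a = max(0.0, float(e @ y) / float(e @ e))
        return a, y - a * e

    def residual(x):
        return amp(x[0])[1]

    starts = np.concatenate([[0.0], _START_GRID])[:, None]
    x, _, ok = _search(residual, [0.0], [RATE_UPPER], starts)
    F = float(x[0])
    a, r = amp(F)
    return FitResult(
        estimator="DPM",
        rates=RateConstants(F=F, k3=math.nan, k4=math.nan, k5=math.nan, k6=math.nan),
        amplitudes=np.array([a]),
        bp=math.nan,
        residual_norm=float(np.linalg.norm(r)),
        n_points=len(curve),
        converged=ok,
    )


def _stain_shape(
    rates: RateConstants, variant: str, probe: str, stain_duration: float
) -> np.ndarray:
    """Relative pool composition at the end of staining, unit delivered load."""
    A_stain = _reduced_generator(rates, variant, probe, washout_active=False)
    e1 = np.zeros(A_stain.shape[0])
    e1[0] = 1.0
    return expm(A_stain * stain_duration) @ e1


def _targeted_fit(
    curve: ConcentrationCurve,
    fixed: dict,
    variant: str,
    opts: SolverOptions | None,
    stain_duration: float,
) -> FitResult:
    """Shared targeted-curve machinery for the DPM and DPM-NS fits.

    DPM solves free non-negative initial amplitudes per pool (its two
    response components — washout-fast free and slow bound — are well
    separated).  DPM-NS instead pins the pool composition at the start of
    rinsing to the stain-phase profile predicted by the candidate rates,
    with one free overall scale (delivery variability): with three pools
    the slow bound and nonspecific responses are nearly collinear over the
    short rinse window, so a free amplitude split — and with it ``k4`` and
    BP — is wildly unstable under measurement noise.  The constraint also
    lets the stain phase inform ``k3`` and ``k4`` through the accumulated
    bound fraction.
    """
    min_pts = 4 if variant == "DPM" else 5
    _validate_curve(curve, "targeted", min_pts)
    t, y = curve.times, curve.values
    use_kaczmarz = variant == "DPM-NS"

    def model(x):
        rates = RateConstants(
            F=fixed["F"], k3=x[0], k4=x[1], k5=fixed.get("k5", 0.0), k6=fixed.get("k6", 0.0)
        )
        A = _reduced_generator(rates, variant, "targeted", washout_active=True)
        if use_kaczmarz:
            # stain-shape constraint, one free scale (see class of fit docstring)
            shape = _stain_shape(rates, variant, "targeted", stain_duration)
            column = _propagate_totals(A, shape[:, None], t)
            c, lin_ok = _ridge_via_kaczmarz(column, y, opts or SolverOptions())
            scale = float(c[0])
            return column[:, 0] * scale - y, scale * shape, lin_ok
        # DPM: free non-negative initial amplitudes per pool
        basis = _total_response_basis(A, t)
        amps, _ = nnls(basis, y)
        return basis @ amps - y, amps, True

    def residual(x):
        return model(x)[0]

    lo = [0.0, K4_FLOOR]
    hi = [RATE_UPPER, RATE_UPPER]
    x, _, ok = _search(
        residual, lo, hi, _multi_starts(2), tie_key=lambda x: x[0] / x[1]
    )
    r, amps, lin_ok = model(x)
    k3, k4 = float(x[0]), float(x[1])
    bp = k3 / k4
    converged = ok and lin_ok

    if k4 <= K4_FLOOR * (1 + 1e-6):
        # Degenerate mode: a never-dissociating bound pool (k4 at the floor)
        # acts as a constant offset that can absorb noise, sending BP = k3/k4
        # to arbitrarily large values.  Compare against the nested null model
        # (k3 = 0, no specific binding, 2 fewer parameters) with a partial
        # F-test; keep the floor solution only if it is significantly better.
        r_null, amps_null, _ = model(np.array([0.0, 1.0]))
        sse1 = float(r @ r)
        sse0 = float(r_null @ r_null)
        dof = len(curve) - 3  # scale + k3 + k4
        from scipy.stats import f as f_dist

        f_stat = ((sse0 - sse1) / 2.0) / (sse1 / dof) if sse1 > 0 and dof > 0 else np.inf
        p = float(f_dist.sf(f_stat, 2, dof)) if np.isfinite(f_stat) else 0.0
        if p >= 0.05:
            k3, k4, bp = 0.0, math.nan, 0.0
            r, amps = r_null, amps_null
        else:
            converged = False  # BP reported at the box constraint

    rates = RateConstants(
        F=fixed["F"],
        k3=k3,
        k4=k4,
        k5=fixed.get("k5", math.nan),
        k6=fixed.get("k6", math.nan),
    )
    return FitResult(
        estimator=variant,
        rates=rates,
        amplitudes=np.asarray(amps),
        bp=bp,
        residual_norm=float(np.linalg.norm(r)),
        n_points=len(curve),
        converged=converged,
    )


def fit_targeted_dpm(
    curve: ConcentrationCurve, F_fixed: float, stain_duration: float = 10.0
) -> FitResult:
    """Estimate ``k3``, ``k4`` and ``BP`` from a targeted curve, ``F`` fixed.

    Two-compartment (free + bound) total with a non-negative
    least-squares amplitude; ``k4`` is floored at ``K4_FLOOR`` so BP stays
    bounded — a fit pinned at the floor is flagged ``converged=False``.
    """
    if F_fixed < 0:
        raise ValueError("F_fixed must be >= 0")
    return _targeted_fit(
        curve, {"F": F_fixed}, "DPM", opts=None, stain_duration=stain_duration
    )


def fit_targeted_dpmns(
    curve: ConcentrationCurve,
    F: float,
    k5: float,
    k6: float,
    opts: SolverOptions | None = None,
    stain_duration: float = 10.0,
) -> FitResult:
    """Estimate ``k3``, ``k4`` and ``BP`` with ``F``, ``k5``, ``k6`` fixed.

    Full three-compartment total; the amplitude coefficient is solved per
    candidate by :func:`kaczmarz_tikhonov_solve`.
    """
    for name, v in (("F", F), ("k5", k5), ("k6", k6)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    return _targeted_fit(
        curve,
        {"F": F, "k5": k5, "k6": k6},
        "DPM-NS",
        opts=opts,
        stain_duration=stain_duration,
    )


def fit_untargeted_dpmns(
    curve: ConcentrationCurve,
    opts: SolverOptions | None = None,
    stain_duration: float = 10.0,
) -> FitResult:
    """Estimate ``F``, ``k5`` and ``k6`` from an untargeted curve.

    The free/nonspecific composition at the start of rinsing is pinned to
    the stain-phase profile predicted by ``(k5, k6)`` over
    ``stain_duration``, leaving one overall scale free (delivery
    variability).  A fully free two-amplitude parametrization is not
    identifiable — the measured biexponential determines only the two
    eigenvalues ``λ1+λ2 = -(F+k5+k6)`` and ``λ1·λ2 = F·k6``, a one-parameter
    family of rate triples — so the stain-phase constraint supplies the
    third equation.
    """
    _validate_curve(curve, "untargeted", 5)
    opts = opts or SolverOptions()
    t, y = curve.times, curve.values

    def model(x):
        rates = RateConstants(F=x[0], k5=x[1], k6=x[2])
        A_stain = _reduced_generator(rates, "DPM-NS", "untargeted", washout_active=False)
        shape = expm(A_stain * stain_duration) @ np.array([1.0, 0.0])
        A_rinse = _reduced_generator(rates, "DPM-NS", "untargeted", washout_active=True)
        column = _propagate_totals(A_rinse, shape[:, None], t)
        c, lin_ok = _ridge_via_kaczmarz(column, y, opts)
        scale = float(c[0])
        return column[:, 0] * scale - y, scale * shape, lin_ok

    def residual(x):
        return model(x)[0]

    lo = [0.0, 0.0, 0.0]
    hi = [RATE_UPPER, RATE_UPPER, RATE_UPPER]
    x, _, ok = _search(residual, lo, hi, _multi_starts(3))
    r, amps, lin_ok = model(x)
    F_hat, k5_hat, k6_hat = (float(v) for v in x)
    converged = ok and lin_ok

    # Parsimony guard at the no-nonspecific-binding boundary: when the data
    # carry no nonspecific component, k6 (and the k5/k6 split) is weakly
    # identified and can wander, poisoning the downstream targeted fit.
    # Keep the full model only if it beats the nested monoexponential
    # washout model (k5 = 0, 2 fewer parameters) by a partial F-test.
    mono = fit_untargeted_dpm(curve)
    sse1 = float(r @ r)
    sse0 = mono.residual_norm**2
    dof = len(curve) - 4  # scale + F + k5 + k6
    from scipy.stats import f as f_dist

    f_stat = ((sse0 - sse1) / 2.0) / (sse1 / dof) if sse1 > 0 and dof > 0 else np.inf
    p = float(f_dist.sf(f_stat, 2, dof)) if np.isfinite(f_stat) else 0.0
    if p >= 0.05:
        F_hat, k5_hat, k6_hat = mono.rates.F, 0.0, 0.0
        amps = np.array([float(mono.amplitudes[0]), 0.0])
        r = np.array([mono.residual_norm])
        converged = mono.converged

    rates = RateConstants(F=F_hat, k3=math.nan, k4=math.nan, k5=k5_hat, k6=k6_hat)
    return FitResult(
        estimator="DPM-NS",
        rates=rates,
        amplitudes=np.asarray(amps),
        bp=math.nan,
        residual_norm=float(np.linalg.norm(r)),
        n_points=len(curve),
        converged=converged,
    )


def predict_totals(result: FitResult, times: np.ndarray) -> np.ndarray:
    """Model total-concentration curve implied by a fit result.

    Reconstructs the rinse-phase model using the fitted rates and the
    fitted initial pool amplitudes; used e.g. as the "clean" curve in
    noise estimation.
    """
    if result.estimator not in ("DPM", "DPM-NS"):
        raise ValueError("only model-based fit results define a fitted curve")
    probe = "untargeted" if math.isnan(result.rates.k3) else "targeted"
    rates = RateConstants(
        F=result.rates.F,
        k3=0.0 if math.isnan(result.rates.k3) else result.rates.k3,
        k4=0.0 if math.isnan(result.rates.k4) else result.rates.k4,
        k5=0.0 if math.isnan(result.rates.k5) else result.rates.k5,
        k6=0.0 if math.isnan(result.rates.k6) else result.rates.k6,
    )
    A = _reduced_generator(rates, result.estimator, probe, washout_active=True)
    x0 = np.atleast_1d(np.asarray(result.amplitudes, dtype=float))
    if x0.shape[0] != A.shape[0]:
        raise ValueError(
            f"amplitude vector of length {x0.shape[0]} does not match the "
            f"{A.shape[0]}-compartment {result.estimator} {probe} model"
        )
    return _propagate_totals(A, x0[:, None], np.asarray(times, dtype=float))[:, 0]


def estimate_bp(
    measurement: DualProbeMeasurement,
    estimator: str,
    opts: SolverOptions | None = None,
    rinse_index: int | None = None,
    stain_duration: float = 10.0,
) -> FitResult:
    """Run one estimator end-to-end on a paired measurement.

    ``Ratio`` evaluates the single-time-point ratio; ``DPM`` and ``DPM-NS``
    run the two-step untargeted-then-targeted fit sequence.
    """
    nan_rates = RateConstants(
        F=math.nan, k3=math.nan, k4=math.nan, k5=math.nan, k6=math.nan
    )
    if estimator == "Ratio":
        bp = bp_ratio(measurement, rinse_index=rinse_index)
        return FitResult(
            estimator="Ratio",
            rates=nan_rates,
            amplitudes=np.array([]),
            bp=bp,
            residual_norm=math.nan,
            n_points=len(measurement.targeted),
            converged=True,
        )
    if estimator == "DPM":
        un = fit_untargeted_dpm(measurement.untargeted)
        return fit_targeted_dpm(
            measurement.targeted, F_fixed=un.rates.F, stain_duration=stain_duration
        )
    if estimator == "DPM-NS":
        un = fit_untargeted_dpmns(
            measurement.untargeted, opts=opts, stain_duration=stain_duration
        )
        return fit_targeted_dpmns(
            measurement.targeted,
            F=un.rates.F,
            k5=un.rates.k5,
            k6=un.rates.k6,
            opts=opts,
            stain_duration=stain_duration,
        )
    raise ValueError(f"unknown estimator {estimator!r}")
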