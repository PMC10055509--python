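"""Spectral graph model (SGM) forward solution.

The SGM expresses the steady-state frequency response of every cortical
region in closed form, as a function of a structural connectome and seven
global (spatially invariant) biophysical parameters: local excitatory and
inhibitory time constants ``tau_e``, ``tau_i``, local neural gains ``g_ei``
and ``g_ii``, a long-range (graph) excitatory time constant ``tau_G``, a
global coupling constant ``alpha``, and a conduction speed ``v``.  Each
region hosts a linearized excitatory–inhibitory circuit; the excitatory
populations are coupled across regions through a frequency-dependent complex
Laplacian whose off-diagonal phases carry conduction delays ``exp(-j w
D/v)``.

The network response at angular frequency ``w = 2*pi*f`` is

    X(w) = sum_k  u_k(w) v_k(w)^H P(w) H_local(w) / (j w + lambda_k(w) F_G(w) / tau_G)

where ``(lambda_k, u_k, v_k)`` are right/left eigenpairs of the complex
Laplacian ``L(w)``, ``F_G`` is the long-range gamma-shaped filter and
``H_local`` the local circuit transfer function.  At full truncation
``K = N`` the sum is exactly the resolvent solve
``(j w I + F_G(w)/tau_G * L(w))^{-1} H_local(w) P(w)``, which is the default
evaluation path.

All frequencies are in Hz at the public surface; time constants in seconds;
conduction speed in m/s; distances in mm.  Power is reported in dB as
``20*log10 |X|``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg

from .connectome import ConnectomeGraph, degree_normalize

logger = logging.getLogger(__name__)

__all__ = [
    "SGMParameters",
    "FrequencyGrid",
    "RegionalSpectrum",
    "PARAM_NAMES",
    "COMMON_BOUNDS",
    "GAIN_BOUNDS_BY_STAGE",
    "stage_bounds",
    "INITIAL_GUESSES",
    "gamma_response",
    "local_transfer",
    "complex_laplacian",
    "forward_spectrum",
    "psd_db",
    "stability_check",
]

# Optimized-parameter order used for every vector interface in the package.
PARAM_NAMES = ("tau_e", "tau_i", "tau_G", "g_ei", "g_ii", "alpha", "speed")

# Box bounds shared by all optimization stages (seconds, dimensionless, m/s).
COMMON_BOUNDS: dict[str, tuple[float, float]] = {
    "tau_e": (0.005, 0.03),
    "tau_i": (0.005, 0.2),
    "tau_G": (0.005, 0.03),
    "alpha": (0.1, 1.0),
    "speed": (5.0, 20.0),
}

# Neural-gain bounds shrink over the three stability stages.
GAIN_BOUNDS_BY_STAGE: dict[int, dict[str, tuple[float, float]]] = {
    1: {"g_ei": (0.001, 0.7), "g_ii": (0.001, 2.0)},
    2: {"g_ei": (0.001, 0.5), "g_ii": (0.001, 1.5)},
    3: {"g_ei": (0.001, 0.4), "g_ii": (0.001, 1.5)},
}


def stage_bounds(stage: int) -> dict[str, tuple[float, float]]:
    """Full bound box (all seven optimized parameters) for a stability stage."""
    if stage not in GAIN_BOUNDS_BY_STAGE:
        raise ValueError(f"stage must be 1, 2 or 3, got {stage}")
    return {**COMMON_BOUNDS, **GAIN_BOUNDS_BY_STAGE[stage]}


@dataclass(frozen=True)
class SGMParameters:
    """The seven optimized SGM parameters plus the fixed excitatory gain.

    Attributes
    ----------
    tau_e, tau_i : float
        Local excitatory / inhibitory ensemble time constants (s).
    tau_G : float
        Long-range (graph) excitatory time constant (s).
    g_ei, g_ii : float
        Alternating excitatory–inhibitory and inhibitory–inhibitory neural
        gains (dimensionless synaptic-strength multipliers).
    alpha : float
        Global coupling constant (dimensionless).
    speed : float
        Conduction speed of long-range signals (m/s).
    g_ee : float
        Excitatory self-gain; a fixed constant of the local circuit, not
        optimized (default 1).
    """

    tau_e: float = 0.015
    tau_i: float = 0.01
    tau_G: float = 0.006
    g_ei: float = 0.3
    g_ii: float = 0.6
    alpha: float = 1.0
    speed: float = 5.0
    g_ee: float = 1.0

    def __post_init__(self) -> None:
        for name in ("tau_e", "tau_i", "tau_G"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.speed <= 0:
            raise ValueError("speed must be strictly positive")

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES])

    @classmethod
    def from_vector(cls, x: np.ndarray, g_ee: float = 1.0) -> "SGMParameters":
        return cls(**dict(zip(PARAM_NAMES, map(float, x))), g_ee=g_ee)

    def within_bounds(self, stage: int = 1) -> bool:
        b = stage_bounds(stage)
        return all(b[n][0] <= getattr(self, n) <= b[n][1] for n in PARAM_NAMES)

    def replace(self, **kw) -> "SGMParameters":
        return replace(self, **kw)

    def as_report_dict(self) -> dict[str, float]:
        """Reporting convention: time constants in milliseconds."""
        return {
            "tau_e_ms": self.tau_e * 1e3,
            "tau_i_ms": self.tau_i * 1e3,
            "tau_G_ms": self.tau_G * 1e3,
            "g_ei": self.g_ei,
            "g_ii": self.g_ii,
            "alpha": self.alpha,
            "speed": self.speed,
        }


# Table of initial guesses used by the staged multi-start optimization.
INITIAL_GUESSES: tuple[SGMParameters, ...] = (
    SGMParameters(tau_e=0.015, tau_i=0.01, tau_G=0.006,
                  g_ei=0.3, g_ii=0.6, alpha=1.0, speed=5.0),
    SGMParameters(tau_e=0.025, tau_i=0.08, tau_G=0.015,
                  g_ei=0.2, g_ii=0.1, alpha=0.5, speed=10.0),
    SGMParameters(tau_e=0.006, tau_i=0.15, tau_G=0.025,
                  g_ei=0.1, g_ii=1.2, alpha=0.1, speed=18.0),
)


@dataclass(frozen=True)
class FrequencyGrid:
    """Ordered evaluation frequencies in Hz; angular form derived on demand."""

    frequencies: np.ndarray

    def __post_init__(self) -> None:
        f = np.atleast_1d(np.asarray(self.frequencies, dtype=float))
        if f.ndim != 1 or f.size == 0:
            raise ValueError("frequencies must be a non-empty 1-D array")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if f[0] < 0:
            raise ValueError("frequencies must be non-negative")
        object.__setattr__(self, "frequencies", f)

    @classmethod
    def default(cls, lo: float = 1.0, hi: float = 35.0,
                step: float = 0.25) -> "FrequencyGrid":
        n = int(round((hi - lo) / step)) + 1
        return cls(np.linspace(lo, hi, n))

    @property
    def omega(self) -> np.ndarray:
        return 2.0 * np.pi * self.frequencies

    def __len__(self) -> int:
        return self.frequencies.size


@dataclass
class RegionalSpectrum:
    """Region x frequency power in dB, empirical or model-generated.

    ``response`` optionally retains the complex frequency response the dB
    values were derived from (model spectra only).
    """

    values: np.ndarray
    grid: FrequencyGrid
    labels: list[str] = field(default_factory=list)
    kind: str = "empirical"
    response: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.grid):
            raise ValueError(
                f"spectrum has {self.values.shape[1]} frequency columns for a "
                f"grid of {len(self.grid)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum values must be finite")
        if not self.labels:
            self.labels = [f"region_{i + 1:04d}" for i in range(self.n_regions)]
        if len(self.labels) != self.n_regions:
            raise ValueError("label count does not match region count")
        if self.kind not in ("model", "empirical"):
            raise ValueError(f"kind must be 'model' or 'empirical', got {self.kind!r}")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# Transfer functions
# ---------------------------------------------------------------------------

def gamma_response(f, tau: float):
    """Gamma-shaped ensemble response filter F(w) = 1 / (1 + j*w*tau)^2.

    The Fourier transform of the normalized gamma kernel
    ``h(t) = t/tau^2 * exp(-t/tau)`` — a second-order low-pass with unit DC
    gain, used for the excitatory, inhibitory and long-range filters.
    """
    if tau <= 0:
        raise ValueError(f"time constant must be positive, got {tau}")
    w = 2.0 * np.pi * np.asarray(f, dtype=float)
    return 1.0 / (1.0 + 1j * w * tau) ** 2


def _local_pieces(f, params: SGMParameters):
    """Numerator and determinant of the local E-I circuit transfer function.

    The circuit linearizes two coupled neural ensembles per region:
    excitatory activity is damped by its own gamma-filtered feedback
    (gain ``g_ee``) and inhibited by the inhibitory population (``g_ei``);
    the inhibitory population is self-damped (``g_ii``) and excited by the
    excitatory one (``g_ei``).  Solving the resulting 2x2 frequency-domain
    system for the total response (X_e + X_i) to a common drive P gives

        H_local = (2 j w + (g_ee - g_ei) F_e/tau_e + (g_ii + g_ei) F_i/tau_i) / Delta
        Delta   = (j w + g_ee F_e/tau_e)(j w + g_ii F_i/tau_i)
                  + g_ei^2 F_e F_i / (tau_e tau_i)

    The alternating-gain loop term ``g_ei^2 F_e F_i`` produces the local
    resonance.
    """
    w = 2.0 * np.pi * np.asarray(f, dtype=float)
    Fe = gamma_response(f, params.tau_e)
    Fi = gamma_response(f, params.tau_i)
    ae = Fe / params.tau_e
    ai = Fi / params.tau_i
    delta = (1j * w + params.g_ee * ae) * (1j * w + params.g_ii * ai) \
        + params.g_ei ** 2 * ae * ai
    numer = 2j * w + (params.g_ee - params.g_ei) * ae + (params.g_ii + params.g_ei) * ai
    return numer, delta


def local_transfer(f, params: SGMParameters):
    """Local excitatory–inhibitory transfer function H_local(w).

    Raises a near-pole error when the circuit determinant magnitude drops
    below 1e-12 at any requested frequency (an unstable or marginally stable
    parameter set).
    """
    numer, delta = _local_pieces(f, params)
    bad = np.abs(delta) < 1e-12
    if np.any(bad):
        f_arr = np.atleast_1d(np.asarray(f, dtype=float))
        f_bad = f_arr[np.atleast_1d(bad)][0] if f_arr.size > 1 else float(f_arr)
        raise FloatingPointError(
            f"local transfer function is near a pole at {f_bad} Hz "
            f"(|denominator| < 1e-12); parameters are unstable"
        )
    return numer / delta


def complex_laplacian(f, graph: ConnectomeGraph, alpha: float, v: float) -> np.ndarray:
    """Complex Laplacian L(w) = I - alpha * N(C o exp(-j w D / v')).

    ``N`` is row-degree normalization by the (real) row sums of C, so the
    zero-frequency limit is the real matrix ``I - alpha * N(C)``; ``v'`` is
    the conduction speed converted to mm/s so that D/v' is in seconds.
    Scalar ``f`` returns an (N, N) matrix; an array of F frequencies returns
    an (F, N, N) stack.
    """
    if v <= 0:
        raise ValueError(f"conduction speed must be positive, got {v}")
    f_arr = np.atleast_1d(np.asarray(f, dtype=float))
    Cn = degree_normalize(graph.C)
    delay = graph.D / (v * 1000.0)  # seconds
    w = 2.0 * np.pi * f_arr[:, None, None]
    A = Cn[None, :, :] * np.exp(-1j * w * delay[None, :, :])
    L = np.eye(graph.N)[None, :, :] - alpha * A
    return L[0] if np.isscalar(f) or np.ndim(f) == 0 else L


def psd_db(X: np.ndarray, floor_db: float = -300.0) -> np.ndarray:
    """Power in dB: 20*log10 |X|, with zeros floored at ``floor_db``."""
    mag = np.abs(np.asarray(X))
    if np.any(mag == 0):
        warnings.warn(
            f"zero-magnitude response floored at {floor_db} dB", RuntimeWarning
        )
    out = np.full(mag.shape, floor_db, dtype=float)
    np.log10(mag, out=out, where=mag > 0)
    out = np.where(mag > 0, 20.0 * out, floor_db)
    return np.maximum(out, floor_db)


def _eigenmode_response(L: np.ndarray, k_used: int,
                        rhs: np.ndarray, omega: float, tau_G: float,
                        FG: complex) -> np.ndarray:
    """Truncated eigenmode sum for one frequency.

    Uses right/left eigenpairs (the spectral projectors of a non-normal
    matrix) normalized to biorthogonality, with modes ordered by ascending
    eigenvalue magnitude so small ``K`` keeps the smoothest network modes.
    """
    lam, vl, vr = scipy.linalg.eig(L, left=True, right=True)
    order = np.argsort(np.abs(lam))
    lam, vl, vr = lam[order], vl[:, order], vr[:, order]
    # biorthogonal normalization: vl_k^H vr_k = 1
    scale = np.einsum("ij,ij->j", vl.conj(), vr)
    if np.any(np.abs(scale) < 1e-12):
        raise np.linalg.LinAlgError("defective complex Laplacian")
    vl = vl / scale.conj()
    coeff = vl.conj().T @ rhs
    denom = 1j * omega + lam[:k_used] * FG / tau_G
    return vr[:, :k_used] @ (coeff[:k_used] / denom)


def forward_spectrum(
    params: SGMParameters,
    graph: ConnectomeGraph,
    grid: FrequencyGrid,
    K: int | None = None,
    drive: np.ndarray | None = None,
    hlocal=None,
    method: str = "auto",
    floor_db: float = -300.0,
) -> RegionalSpectrum:
    """Closed-form SGM frequency response of all regions.

    Parameters
    ----------
    K : int, optional
        Eigenmode truncation order; default N (exact).  At ``K = N`` the
        response is evaluated by a direct resolvent solve, mathematically
        identical to the full eigenmode sum.
    drive : ndarray, optional
        Per-region input spectrum P(w), shape (N,) or (N, F); default unit
        white drive.
    hlocal : callable, optional
        Replacement local transfer function ``hlocal(f, params)``; the test
        hook ``lambda f, p: 1.0`` reduces the model to the pure network
        response.
    method : {"auto", "solve", "eig"}
        "solve" forces the resolvent path (requires K = N); "eig" forces the
        eigenmode sum; "auto" picks "solve" at full truncation.

    Returns
    -------
    RegionalSpectrum
        dB power (kind="model") with the complex response retained in
        ``.response``.
    """
    N = graph.N
    K = N if K is None else int(K)
    if not 1 <= K <= N:
        raise ValueError(f"truncation order K={K} outside [1, {N}]")
    if method not in ("auto", "solve", "eig"):
        raise ValueError(f"unknown method {method!r}")
    if method == "solve" and K != N:
        raise ValueError("method='solve' requires full truncation K = N")
    use_solve = (method == "solve") or (method == "auto" and K == N)

    freqs = grid.frequencies
    F = len(grid)
    if drive is None:
        drive = np.ones((N, F))
    else:
        drive = np.asarray(drive, dtype=complex)
        if drive.ndim == 1:
            drive = np.repeat(drive[:, None], F, axis=1)
        if drive.shape != (N, F):
            raise ValueError(f"drive must have shape ({N},) or ({N}, {F})")

    hloc_fun = hlocal if hlocal is not None else local_transfer
    Hloc = np.asarray(hloc_fun(freqs, params)) * np.ones(F, dtype=complex)
    FG = gamma_response(freqs, params.tau_G)
    omega = grid.omega

    L = complex_laplacian(freqs, graph, params.alpha, params.speed)  # (F,N,N)
    rhs = (drive * Hloc[None, :]).T[:, :, None]  # (F,N,1)

    if use_solve:
        # (j w I + FG/tau_G * L) X = H_local P  — batched over frequencies
        A = (1j * omega)[:, None, None] * np.eye(N)[None, :, :] \
            + (FG / params.tau_G)[:, None, None] * L
        X = np.linalg.solve(A, rhs)[:, :, 0].T  # (N,F)
    else:
        X = np.empty((N, F), dtype=complex)
        for i in range(F):
            try:
                X[:, i] = _eigenmode_response(
                    L[i], K, rhs[i, :, 0], omega[i], params.tau_G, FG[i]
                )
            except np.linalg.LinAlgError:
                logger.warning(
                    "eigen-decomposition failed at %.3f Hz; "
                    "falling back to direct solve", freqs[i]
                )
                A = 1j * omega[i] * np.eye(N) + FG[i] / params.tau_G * L[i]
                X[:, i] = np.linalg.solve(A, rhs[i, :, 0])

    values = psd_db(X, floor_db=floor_db)
    return RegionalSpectrum(values=values, grid=grid, labels=list(graph.labels),
                            kind="model", response=X)


# ---------------------------------------------------------------------------
# Stability
# ---------------------------------------------------------------------------

#: dense frequency grid over which the local denominator is scanned
_STABILITY_GRID = np.linspace(0.1, 100.0, 1000)


def local_characteristic_roots(params: SGMParameters) -> np.ndarray:
    """Roots of the local circuit's characteristic polynomial in s.

    Clearing the gamma-kernel denominators from the circuit determinant
    gives the degree-6 polynomial

        (s (1 + s tau_e)^2 + g_ee/tau_e) (s (1 + s tau_i)^2 + g_ii/tau_i)
            + g_ei^2 / (tau_e tau_i)

    whose roots are the poles of H_local; the response is bounded iff all
    real parts are negative.
    """
    P = np.polynomial.Polynomial
    te, ti = params.tau_e, params.tau_i
    p1 = P([params.g_ee / te, 1.0, 2.0 * te, te ** 2])
    p2 = P([params.g_ii / ti, 1.0, 2.0 * ti, ti ** 2])
    return (p1 * p2 + P([params.g_ei ** 2 / (te * ti)])).roots()


def stability_check(
    params: SGMParameters,
    stage: int = 1,
    denom_tol: float = 1e-6,
) -> tuple[bool, dict]:
    """Verdict on whether a parameter set yields a bounded model response.

    Criteria: (a) the neural gains lie within the requested stage's bounds;
    (b) the response is bounded — the local circuit determinant magnitude
    stays above ``denom_tol`` on a dense 0.1–100 Hz grid (no pole near the
    real frequency axis) and every root of the circuit's characteristic
    polynomial has negative real part (no pole anywhere in the right half
    plane).  Returns ``(stable, diagnostics)``; never raises.
    """
    diag: dict = {"stage": stage}
    b = stage_bounds(stage)
    in_bounds = all(
        b[n][0] <= getattr(params, n) <= b[n][1] for n in ("g_ei", "g_ii")
    )
    diag["gains_in_bounds"] = bool(in_bounds)
    _, delta = _local_pieces(_STABILITY_GRID, params)
    min_denom = float(np.min(np.abs(delta)))
    diag["min_denominator"] = min_denom
    diag["denominator_ok"] = bool(min_denom > denom_tol)
    roots = local_characteristic_roots(params)
    diag["max_pole_real"] = float(roots.real.max())
    diag["poles_in_lhp"] = bool(roots.real.max() < 0)
    stable = (diag["gains_in_bounds"] and diag["denominator_ok"]
              and diag["poles_in_lhp"])
    if not stable:
        diag["failed"] = [
            k for k in ("gains_in_bounds", "denominator_ok", "poles_in_lhp")
            if not diag[k]
        ]
    return stable, diag
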