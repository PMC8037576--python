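"""ThT aggregation-kinetics statistics and the secondary-nucleation-dominated
rate model.

Normalized fibrillar mass M(t) in [0, 1] is derived from raw fluorescence by
baseline/plateau normalization.  Summary statistics follow the operational
definitions used for amyloid plate-reader data:

* ``t_half`` - first upward crossing of M = 0.5, linearly interpolated.
* ``t_lag``  - the highest *measured* time (no interpolation) at which
  M < 0.10, restricted to times at or before ``t_half`` so that noisy
  post-plateau dips are ignored.
* ``delta_t_half`` - t_half(condition) - t_half(control), the inhibitor
  effect readout.

The rate model is the analytical secondary-nucleation-dominated solution
with effective rates

    kappa  = sqrt(2 k_plus k2 m0^(n2+1))     (secondary pathways)
    lambda = sqrt(2 k_plus kn m0^(nc))       (primary nucleation)

and the standard composite-exponential closed form; from a single normalized
curve only (kappa, lambda) are identifiable, so fitting treats those as the
free parameters (reaction orders fixed, default nc = n2 = 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, least_squares


@dataclass
class KineticTrace:
    """Raw fluorescence vs time (s); arbitrary units."""

    times: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.signal.shape:
            raise ValueError("times and signal must be congruent 1-D arrays")
        if len(self.times) < 10:
            raise ValueError("need at least 10 samples")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class NormalizedTrace:
    """Normalized fibrillar-mass curve; nominally in [0, 1] (noise may exceed)."""

    times: np.ndarray
    mass_fraction: np.ndarray


@dataclass
class KineticSummary:
    t_half: float
    t_lag: float
    delta_t_half: float | None = None


@dataclass
class SecondaryNucleationParams:
    """Rates for the secondary-nucleation-dominated model.

    ``m0`` in M; ``k_n`` (primary nucleation), ``k_plus`` (elongation) and
    ``k2`` (secondary nucleation) in units consistent with the reaction
    orders ``n_c`` and ``n2``.
    """

    m0: float
    k_n: float
    k_plus: float
    k2: float
    n_c: float = 2.0
    n2: float = 2.0

    def __post_init__(self) -> None:
        for name in ("m0", "k_n", "k_plus", "k2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_c < 1 or self.n2 < 1:
            raise ValueError("reaction orders must be >= 1")

    @property
    def kappa(self) -> float:
        return float(np.sqrt(2.0 * self.k_plus * self.k2 * self.m0 ** (self.n2 + 1.0)))

    @property
    def lam(self) -> float:
        return float(np.sqrt(2.0 * self.k_plus * self.k_n * self.m0 ** self.n_c))

    @classmethod
    def from_effective_rates(
        cls, kappa: float, lam: float, m0: float = 5e-6,
        n_c: float = 2.0, n2: float = 2.0,
    ) -> "SecondaryNucleationParams":
        """Build params from the identifiable (kappa, lambda) pair with the
        elongation rate fixed at 1 (single-curve convention)."""
        k_plus = 1.0
        k2 = kappa**2 / (2.0 * k_plus * m0 ** (n2 + 1.0))
        k_n = lam**2 / (2.0 * k_plus * m0**n_c)
        return cls(m0=m0, k_n=k_n, k_plus=k_plus, k2=k2, n_c=n_c, n2=n2)


def normalize(
    trace: KineticTrace,
    baseline_window: slice | None = None,
    plateau_window: slice | None = None,
) -> NormalizedTrace:
    """Baseline/plateau normalization of a raw ThT trace.

    Windows default to the first and last 10% of the samples (at least 3
    samples each).  The normalized curve has baseline mean 0 and plateau
    mean 1 by construction.
    """
    n = len(trace.times)
    tenth = max(3, n // 10)
    baseline_window = baseline_window or slice(0, tenth)
    plateau_window = plateau_window or slice(n - tenth, n)
    b_idx = np.arange(n)[baseline_window]
    p_idx = np.arange(n)[plateau_window]
    if len(b_idx) < 3 or len(p_idx) < 3:
        raise ValueError("normalization windows need >= 3 samples each")
    if np.intersect1d(b_idx, p_idx).size:
        raise ValueError("baseline and plateau windows overlap")
    b = float(np.mean(trace.signal[b_idx]))
    p = float(np.mean(trace.signal[p_idx]))
    if p <= b:
        raise ValueError("plateau mean <= baseline mean: no aggregation transition")
    return NormalizedTrace(times=trace.times.copy(), mass_fraction=(trace.signal - b) / (p - b))


def half_time(normalized: NormalizedTrace) -> float:
    """First upward crossing of 0.5, linearly interpolated (s)."""
    m = normalized.mass_fraction
    t = normalized.times
    for i in range(1, len(m)):
        if m[i - 1] < 0.5 <= m[i]:
            frac = (0.5 - m[i - 1]) / (m[i] - m[i - 1])
            return float(t[i - 1] + frac * (t[i] - t[i - 1]))
    raise ValueError("trace never reaches 50% fibrillar mass")


def lag_time(normalized: NormalizedTrace, threshold: float = 0.10) -> float:
    """Highest measured time with mass below ``threshold``, at or before the
    half-time (a measured sample time is returned, not an interpolation)."""
    t_half = half_time(normalized)
    m = normalized.mass_fraction
    t = normalized.times
    eligible = (t <= t_half) & (m < threshold)
    if not eligible.any():
        raise ValueError(f"no pre-transition sample below {threshold:.0%}")
    return float(t[eligible].max())


def delta_half_time(condition: KineticSummary, control: KineticSummary) -> float:
    """Inhibitor-induced half-time shift, condition minus control (s)."""
    return condition.t_half - control.t_half


def summarize(normalized: NormalizedTrace, control: KineticSummary | None = None) -> KineticSummary:
    t50 = half_time(normalized)
    tl = lag_time(normalized)
    out = KineticSummary(t_half=t50, t_lag=tl)
    if control is not None:
        out.delta_t_half = delta_half_time(out, control)
    return out


# ---------------------------------------------------------------------------
# Secondary-nucleation-dominated closed form
# ---------------------------------------------------------------------------

def _effective_mass_fraction(kappa: float, lam: float, n_c: float, n2: float,
                             t: np.ndarray) -> np.ndarray:
    if kappa <= 0 or lam <= 0:
        raise ValueError("kappa and lambda must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    c_plus = lam**2 / (2.0 * kappa**2)
    c_minus = -c_plus
    k_inf = np.sqrt(2.0 * kappa**2 / (n2 * (n2 + 1.0)) + 2.0 * lam**2 / n_c)
    k_tilde = np.sqrt(k_inf**2 - 4.0 * c_plus * c_minus * kappa**2)
    b_plus = (k_inf + k_tilde) / (2.0 * kappa)
    b_minus = (k_inf - k_tilde) / (2.0 * kappa)
    # R(t) = [(B+ + C+)/(B+ + C+ e^{kt})] * [(B- + C+ e^{kt})/(B- + C+)]
    # computed with y = e^{-kt} to avoid overflow:
    # (B- + C+e^{kt})/(B+ + C+e^{kt}) = (B- y + C+)/(B+ y + C+)
    y = np.exp(-kappa * t)
    ratio = (b_minus * y + c_plus) / (b_plus * y + c_plus)
    r = ratio * (b_plus + c_plus) / (b_minus + c_plus)
    exponent = k_inf**2 / (kappa * k_tilde)
    if np.any(r <= 0):
        raise ValueError("model parameters outside the secondary-dominated regime")
    m = 1.0 - np.power(r, exponent) * np.exp(-k_inf * t)
    return np.clip(m, 0.0, 1.0)


def model_mass_fraction(params: SecondaryNucleationParams, t: np.ndarray) -> np.ndarray:
    """Normalized fibrillar mass M(t) of the secondary-nucleation-dominated
    model; M(0) = 0, non-decreasing, M(inf) = 1."""
    return _effective_mass_fraction(params.kappa, params.lam, params.n_c, params.n2, t)


def model_half_time(kappa: float, lam: float, n_c: float = 2.0, n2: float = 2.0) -> float:
    """Half-time of the noise-free model curve (s), by root bracketing."""

    def f(t: float) -> float:
        return float(_effective_mass_fraction(kappa, lam, n_c, n2, np.array([t]))[0]) - 0.5

    hi = 1.0 / kappa
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e12 / kappa:
            raise ValueError("half-time bracketing failed")
    return float(brentq(f, 0.0, hi, xtol=1e-6 / kappa))


@dataclass
class FitResult:
    params: SecondaryNucleationParams
    kappa: float
    lam: float
    residual_norm: float
    success: bool
    message: str


def fit_model(
    traces: list[NormalizedTrace],
    m0: float = 5e-6,
    n_c: float = 2.0,
    n2: float = 2.0,
    initial: tuple[float, float] | None = None,
) -> FitResult:
    """Least-squares fit of (kappa, lambda) to one or more normalized traces.

    A coarse log-grid around a half-time heuristic seeds a trust-region
    refinement in (log kappa, log lambda).  Raises on degenerate input (a
    trace that never transitions) and on non-convergence.
    """
    if not traces:
        raise ValueError("need at least one trace")
    times = np.concatenate([tr.times for tr in traces])
    mass = np.concatenate([tr.mass_fraction for tr in traces])

    try:
        t50s = [half_time(tr) for tr in traces]
    except ValueError as exc:
        raise ValueError(f"degenerate trace: {exc}") from exc
    t50 = float(np.mean(t50s))

    def sse(log_k: float, log_l: float) -> float:
        try:
            pred = _effective_mass_fraction(10.0**log_k, 10.0**log_l, n_c, n2, times)
        except (ValueError, FloatingPointError):
            return np.inf
        return float(np.sum((mass - pred) ** 2))

    if initial is not None:
        best = (np.log10(initial[0]), np.log10(initial[1]))
    else:
        centre = np.log10(2.0 / t50)
        best, best_val = None, np.inf
        for lk in np.linspace(centre - 1.2, centre + 1.2, 25):
            for dl in np.linspace(0.3, 4.0, 16):
                val = sse(lk, lk - dl)
                if val < best_val:
                    best, best_val = (lk, lk - dl), val
        if best is None or not np.isfinite(best_val):
            raise ValueError("could not find a feasible starting point")

    def residuals(x: np.ndarray) -> np.ndarray:
        try:
            pred = _effective_mass_fraction(10.0 ** x[0], 10.0 ** x[1], n_c, n2, times)
        except ValueError:
            return np.full_like(mass, 1e3)
        return mass - pred

    sol = least_squares(residuals, x0=np.array(best), method="lm", xtol=1e-14, ftol=1e-14)
    if not sol.success:
        raise RuntimeError(f"fit did not converge: {sol.message} (last iterate {sol.x})")
    kappa, lam = float(10.0 ** sol.x[0]), float(10.0 ** sol.x[1])
    params = SecondaryNucleationParams.from_effective_rates(kappa, lam, m0=m0, n_c=n_c, n2=n2)
    return FitResult(
        params=params,
        kappa=kappa,
        lam=lam,
        residual_norm=float(np.linalg.norm(sol.fun)),
        success=bool(sol.success),
        message=str(sol.message),
    )
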