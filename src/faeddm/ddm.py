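"""Wiener diffusion first-passage-time kernel.

A drift-diffusion trial is a Brownian motion with drift ``v`` and unit
diffusion coefficient, started at ``b * a`` between absorbing boundaries at
``0`` (female response) and ``a`` (male response).  The first boundary hit
determines the choice; the hitting time plus the non-decision time ``t``
gives the reaction time.  The diffusion coefficient is fixed at 1 — the
usual scaling convention for this parameterisation — so ``a``, ``v`` are
interpreted on that scale.

Three entry points:

* :func:`wfpt_logpdf` / :func:`wfpt_density` — the defective first-passage
  density over (choice, rt), evaluated with the two complementary series
  expansions (small-time and large-time) and an automatic, truncation-
  error-bounded switch between them.
* :func:`choice_probability` — closed-form probability of absorption at the
  upper (male) boundary.
* :func:`simulate_trials` / :func:`simulate_trial` — Euler–Maruyama
  simulation with a boundary continuity correction for the discrete
  monitoring bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from faeddm.conventions import CHOICE_LOWER, CHOICE_UPPER, ConfigError, DomainError

__all__ = [
    "DDMParameters",
    "SignedResponse",
    "wfpt_logpdf",
    "wfpt_density",
    "choice_probability",
    "simulate_trial",
    "simulate_trials",
]

#: Per-evaluation truncation-error bound for the series expansions.
SERIES_ERR = 1e-10

#: Continuity-correction constant zeta(1/2)/sqrt(2*pi) (Broadie–Glasserman):
#: discretely monitored boundaries are pulled inward by BG_BETA*sqrt(dt) to
#: emulate continuous absorption.
BG_BETA = 0.5826


@dataclass(frozen=True)
class DDMParameters:
    """One subject-condition diffusion parameter set.

    Parameters
    ----------
    a : float
        Boundary separation (> 0); the amount of evidence needed to decide.
    t : float
        Non-decision time in seconds (>= 0): encoding + motor execution.
    b : float
        Relative start point in (0, 1), as a fraction of ``a``; 0.5 is
        unbiased, values above 0.5 favour the upper (male) boundary.
    v : float
        Drift rate (evidence units per second); positive drifts point to
        the upper (male) boundary.
    """

    a: float
    t: float
    b: float
    v: float

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise DomainError(f"boundary separation a must be > 0, got {self.a}")
        if not (0 < self.b < 1):
            raise DomainError(f"start point b must lie in (0, 1), got {self.b}")
        if not (self.t >= 0):
            raise DomainError(f"non-decision time t must be >= 0, got {self.t}")


@dataclass(frozen=True)
class SignedResponse:
    """A (choice, rt) pair; choice +1 = upper/male, -1 = lower/female."""

    choice: int
    rt: float

    def __post_init__(self) -> None:
        if self.choice not in (CHOICE_UPPER, CHOICE_LOWER):
            raise DomainError(f"choice must be +1 or -1, got {self.choice}")
        if not (self.rt > 0):
            raise DomainError(f"rt must be positive, got {self.rt}")

    @property
    def signed_rt(self) -> float:
        """Reaction time signed by the response (+ male, - female)."""
        return self.choice * self.rt


def _validate_arrays(a, t, b, v) -> None:
    if np.any(a <= 0):
        raise DomainError("boundary separation a must be > 0")
    if np.any((b <= 0) | (b >= 1)):
        raise DomainError("start point b must lie in (0, 1)")
    if np.any(t < 0):
        raise DomainError("non-decision time t must be >= 0")
    if np.any(~np.isfinite(v)):
        raise DomainError("drift rate v must be finite")


def wfpt_logpdf(rt, choice, a, t, b, v, err: float = SERIES_ERR) -> np.ndarray:
    """Log of the defective Wiener first-passage density, vectorised.

    Parameters broadcast against each other.  ``choice`` is +1 for the
    upper (male) and -1 for the lower (female) boundary.  Returns ``-inf``
    where ``rt <= t`` (no decision time available for diffusion).

    The density for the lower boundary with start fraction ``w`` is
    ``f(rt) = f0((rt-t)/a^2; w) * exp(-v*a*w - v^2*(rt-t)/2) / a^2`` where
    ``f0`` is the standardised first-passage density, evaluated by the
    small-time or large-time series, whichever needs fewer terms for a
    truncation error below ``err``.  The upper boundary follows by the
    reflection ``(v, b) -> (-v, 1-b)``.
    """
    rt, choice, a, t, b, v = np.broadcast_arrays(
        *[np.asarray(x, dtype=float) for x in (rt, choice, a, t, b, v)]
    )
    if np.any(rt <= 0):
        raise DomainError("rt must be positive")
    _validate_arrays(a, t, b, v)

    out = np.full(rt.shape, -np.inf)
    u = rt - t
    ok = u > 0
    if not np.any(ok):
        return out

    u = u[ok]
    aa = a[ok]
    # reflect upper-boundary evaluations onto the lower-boundary formula
    up = choice[ok] > 0
    w = np.where(up, 1.0 - b[ok], b[ok])
    vv = np.where(up, -v[ok], v[ok])

    tt = u / aa**2  # standardised time

    # number of series terms needed for error < err (Navarro & Fuss bounds)
    with np.errstate(divide="ignore", invalid="ignore"):
        arg_s = 2.0 * np.sqrt(2.0 * np.pi * tt) * err
        ks = np.where(
            arg_s < 1.0,
            2.0 + np.sqrt(np.maximum(-2.0 * tt * np.log(arg_s), 0.0)),
            2.0,
        )
        ks = np.maximum(ks, np.sqrt(tt) + 1.0)
        arg_l = np.pi * tt * err
        kl = np.where(
            arg_l < 1.0,
            np.sqrt(np.maximum(-2.0 * np.log(arg_l), 0.0) / (np.pi**2 * tt)),
            0.0,
        )
        kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(tt)))

    small = ks < kl
    f0 = np.empty_like(tt)

    if np.any(small):
        tts, ws = tt[small], w[small]
        K = int(np.ceil(ks[small].max()))
        ksum = np.zeros_like(tts)
        for k in range(-((K - 1) // 2), ((K - 1) // 2) + ((K - 1) % 2) + 1):
            wk = ws + 2.0 * k
            ksum += wk * np.exp(-(wk**2) / (2.0 * tts))
        f0[small] = ksum / np.sqrt(2.0 * np.pi * tts**3)

    if np.any(~small):
        ttl, wl = tt[~small], w[~small]
        K = int(np.ceil(kl[~small].max()))
        ksum = np.zeros_like(ttl)
        for k in range(1, K + 1):
            ksum += k * np.exp(-(k**2) * np.pi**2 * ttl / 2.0) * np.sin(k * np.pi * wl)
        f0[~small] = np.pi * ksum

    # scale back and apply the drift factor
    dens = f0 * np.exp(-vv * aa * w - vv**2 * u / 2.0) / aa**2
    with np.errstate(divide="ignore"):
        out[ok] = np.where(dens > 0, np.log(np.maximum(dens, 1e-300)), -np.inf)
    return out


def wfpt_density(response: SignedResponse, params: DDMParameters) -> float:
    """Defective first-passage density (per second) at one (choice, rt).

    Returns 0 for reaction times at or below the non-decision time.
    Integrating over rt for both boundaries sums to 1.
    """
    if response.rt <= params.t:
        return 0.0
    lp = wfpt_logpdf(
        response.rt, response.choice, params.a, params.t, params.b, params.v
    )
    return float(np.exp(lp))


def choice_probability(params: DDMParameters | None = None, *, a=None, b=None, v=None):
    """Probability of absorption at the upper (male) boundary.

    Closed form for the absorbing-barrier problem with unit diffusion:
    ``P(upper) = expm1(-2*v*a*b) / expm1(-2*v*a)`` with the drift-free
    limit ``P(upper) = b`` handled analytically.  Accepts either a
    :class:`DDMParameters` or broadcastable arrays ``a, b, v``.
    """
    if params is not None:
        a, b, v = params.a, params.b, params.v
        scalar = True
    else:
        scalar = np.isscalar(a) and np.isscalar(b) and np.isscalar(v)
    a, b, v = np.broadcast_arrays(
        *[np.asarray(x, dtype=float) for x in (a, b, v)]
    )
    _validate_arrays(a, np.zeros_like(a), b, v)
    va = v * a
    tiny = np.abs(va) < 1e-9
    p = np.empty_like(a)
    with np.errstate(over="ignore"):
        safe = np.where(tiny, 1.0, va)
        num = np.expm1(-2.0 * safe * b)
        den = np.expm1(-2.0 * safe)
        p = np.where(tiny, b + va * b * (1.0 - b), num / den)
    p = np.clip(p, 0.0, 1.0)
    return float(p) if scalar else p


def simulate_trials(
    n: int,
    a,
    t,
    b,
    v,
    rng: np.random.Generator,
    resolution: float = 1e-4,
    max_time: float = 60.0,
    continuity_correction: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``n`` diffusion trials; returns (choices, rts).

    Euler–Maruyama with step ``resolution`` (seconds).  With
    ``continuity_correction`` the absorbing boundaries are pulled inward by
    ``0.5826*sqrt(dt)`` so that the discrete-monitoring first-passage bias
    is O(dt) instead of O(sqrt(dt)).  Parameters may be scalars or length-n
    arrays.  Trials still unabsorbed at ``max_time`` (vanishing probability
    for sensible parameters) are assigned the nearer boundary.
    """
    if not (resolution > 0):
        raise ConfigError(f"resolution must be positive, got {resolution}")
    dt = float(resolution)
    a, t, b, v = [np.broadcast_to(np.asarray(x, dtype=float), (n,)) for x in (a, t, b, v)]
    _validate_arrays(a, t, b, v)

    corr = BG_BETA * np.sqrt(dt) if continuity_correction else 0.0
    upper = a - corr
    lower = np.full(n, corr)
    if np.any(upper <= lower):
        raise ConfigError("resolution too coarse for this boundary separation")

    x = np.clip(b * a, lower + 1e-12, upper - 1e-12)
    choices = np.zeros(n, dtype=np.int64)
    steps = np.zeros(n, dtype=np.int64)
    alive = np.arange(n)
    x_alive = x.copy()
    done_steps = 0
    max_steps = int(np.ceil(max_time / dt))
    sqdt = np.sqrt(dt)

    while alive.size and done_steps < max_steps:
        m = alive.size
        # block size capped so the noise matrix stays small in memory
        block = int(max(8, min(256, 4_000_000 // max(m, 1))))
        block = min(block, max_steps - done_steps)
        incr = v[alive, None] * dt + sqdt * rng.standard_normal((m, block))
        path = x_alive[:, None] + np.cumsum(incr, axis=1)
        hit_up = path >= upper[alive, None]
        hit_lo = path <= lower[alive, None]
        hit = hit_up | hit_lo
        any_hit = hit.any(axis=1)
        first = np.argmax(hit, axis=1)
        rows = np.nonzero(any_hit)[0]
        if rows.size:
            idx = alive[rows]
            steps[idx] = done_steps + first[rows] + 1
            choices[idx] = np.where(
                hit_up[rows, first[rows]], CHOICE_UPPER, CHOICE_LOWER
            )
        keep = ~any_hit
        x_alive = path[keep, -1]
        alive = alive[keep]
        done_steps += block

    if alive.size:  # timed out: assign the nearer boundary
        mid = (upper[alive] + lower[alive]) / 2.0
        choices[alive] = np.where(x_alive >= mid, CHOICE_UPPER, CHOICE_LOWER)
        steps[alive] = max_steps

    rts = t + steps * dt
    return choices, rts


def simulate_trial(
    params: DDMParameters,
    rng: np.random.Generator,
    resolution: float = 1e-4,
) -> SignedResponse:
    """Simulate a single trial; rt is always >= t + resolution."""
    ch, rt = simulate_trials(
        1, params.a, params.t, params.b, params.v, rng, resolution=resolution
    )
    return SignedResponse(choice=int(ch[0]), rt=float(rt[0]))
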