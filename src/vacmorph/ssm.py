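"""Bayesian state-space model for NCC time series.

System model: the control-group mean follows a Normal random walk,
``mu[t] ~ Normal(mu[t-1], sigma_mu)``, and the group difference follows a
Cauchy random walk, ``delta[t] ~ Cauchy(delta[t-1], sigma_delta)``
(t = 2..T). Observation model: every control replicate at time t is
``BetaProportion(mu[t], kappa)`` and every experimental replicate is
``BetaProportion(mu[t] + delta[t], kappa)``, where
``BetaProportion(theta | m, kappa) = Beta(m*kappa, (1-m)*kappa)``.

Priors are the sampling software's defaults: uniform over the constrained
support of each parameter (mu in (0,1), mu+delta in (0,1), positive
scales), implemented by adding the log Jacobian of the usual constraining
transforms to the unconstrained-space target.

Sampling is by NUTS (no-U-turn sampler) with dual-averaging step-size
adaptation and a diagonal mass matrix estimated during warmup, using the
analytic gradient of the log posterior. Convergence is summarized with
split-R-hat and bulk effective sample size (via ``arviz``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, expit, gammaln, logit

__all__ = [
    "SSMData",
    "SSMParams",
    "SSMPosterior",
    "SamplerSettings",
    "beta_proportion_logpdf",
    "cauchy_logpdf",
    "log_posterior",
    "sample_posterior",
    "summarize",
]

_CLIP = 1e-6  # observations outside (0,1) are clipped to [_CLIP, 1-_CLIP]


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------


def beta_proportion_logpdf(theta, mu, kappa):
    """Log density of BetaProportion(theta | mu, kappa) = Beta(mu*k, (1-mu)*k).

    ``theta`` outside (0, 1) gives ``-inf``; invalid ``mu`` or ``kappa``
    raises. Broadcasts like a numpy ufunc.
    """
    theta = np.asarray(theta, dtype=float)
    mu = np.asarray(mu, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    if np.any((mu <= 0) | (mu >= 1)):
        raise ValueError("mu must lie in (0, 1)")
    if np.any(kappa <= 0):
        raise ValueError("kappa must be positive")
    a = mu * kappa
    b = (1.0 - mu) * kappa
    inside = (theta > 0) & (theta < 1)
    th = np.where(inside, theta, 0.5)
    lbeta = gammaln(a) + gammaln(b) - gammaln(a + b)
    out = -lbeta + (a - 1.0) * np.log(th) + (b - 1.0) * np.log1p(-th)
    out = np.where(inside, out, -np.inf)
    return out if out.ndim else float(out)


def cauchy_logpdf(theta, mu, sigma):
    """Log density of Cauchy(theta | mu, sigma) = 1/(pi*sigma) / (1+((theta-mu)/sigma)^2)."""
    theta = np.asarray(theta, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    z = (theta - np.asarray(mu, dtype=float)) / sigma
    out = -np.log(np.pi * sigma) - np.log1p(z * z)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# data and parameter containers
# ---------------------------------------------------------------------------


@dataclass
class SSMData:
    """Replicate NCC observations per time point for two groups.

    ``control`` and ``experimental`` are lists of 1-D arrays, one per
    modeled time point (missing values already removed, remaining values in
    the open unit interval).
    """

    control: list[np.ndarray]
    experimental: list[np.ndarray]
    times_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.control) != len(self.experimental):
            raise ValueError("groups must cover the same time points")
        if len(self.control) < 2:
            raise ValueError("need at least T = 2 time points")
        self.control = [np.asarray(v, dtype=float).ravel() for v in self.control]
        self.experimental = [
            np.asarray(v, dtype=float).ravel() for v in self.experimental
        ]
        for group in (self.control, self.experimental):
            for v in group:
                if np.any((v <= 0) | (v >= 1)):
                    raise ValueError(
                        "observations must lie in (0, 1); apply the clipping policy"
                    )
        if sum(v.size for v in self.control) == 0 or sum(
            v.size for v in self.experimental
        ) == 0:
            raise ValueError("each group needs at least one observation")

    @property
    def T(self) -> int:
        return len(self.control)

    @classmethod
    def from_arrays(
        cls,
        control: np.ndarray,
        experimental: np.ndarray,
        times_s: np.ndarray | None = None,
        drop_first: bool = False,
    ) -> "SSMData":
        """Build from ``(n_cells, T)`` arrays; NaNs are dropped per time point.

        ``drop_first=True`` removes the t = 0 column (the self-comparison
        NCC of exactly 1, which lies outside the Beta support); any residual
        value outside (0, 1) is clipped with a warning.
        """
        control = np.atleast_2d(np.asarray(control, dtype=float))
        experimental = np.atleast_2d(np.asarray(experimental, dtype=float))
        if drop_first:
            control = control[:, 1:]
            experimental = experimental[:, 1:]
            times_s = None if times_s is None else np.asarray(times_s)[1:]
        if control.shape[1] != experimental.shape[1]:
            raise ValueError("groups must have the same number of time points")

        def _columns(arr):
            cols = []
            clipped = 0
            for t in range(arr.shape[1]):
                v = arr[:, t]
                v = v[np.isfinite(v)]
                bad = (v <= 0) | (v >= 1)
                clipped += int(bad.sum())
                cols.append(np.clip(v, _CLIP, 1.0 - _CLIP))
            return cols, clipped

        ctrl, nc = _columns(control)
        expe, ne = _columns(experimental)
        if nc + ne:
            warnings.warn(
                f"clipped {nc + ne} observations into ({_CLIP}, {1 - _CLIP})",
                UserWarning,
                stacklevel=2,
            )
        return cls(ctrl, expe, times_s=times_s)

    @classmethod
    def from_series(
        cls, series_list, control_condition: str, experimental_condition: str
    ) -> "SSMData":
        """Build from :class:`~vacmorph.morphodynamics.NCCSeries` objects.

        The t = 0 entry of each series (NCC = 1 by construction) is
        excluded from fitting.
        """
        ctrl = [s for s in series_list if s.condition == control_condition]
        expe = [s for s in series_list if s.condition == experimental_condition]
        if not ctrl or not expe:
            raise ValueError("both conditions must be present in the series list")
        times = ctrl[0].times_s
        for s in ctrl + expe:
            if not np.array_equal(s.times_s, times):
                raise ValueError("all series must share the same time grid")
        return cls.from_arrays(
            np.stack([s.values for s in ctrl]),
            np.stack([s.values for s in expe]),
            times_s=times,
            drop_first=True,
        )


@dataclass
class SSMParams:
    """One point in parameter space (constrained scale)."""

    mu: np.ndarray
    delta: np.ndarray
    sigma_mu: float
    sigma_delta: float
    kappa: float

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        if self.mu.shape != self.delta.shape or self.mu.ndim != 1:
            raise ValueError("mu and delta must be 1-D vectors of equal length")

    def in_support(self) -> bool:
        nu = self.mu + self.delta
        return bool(
            np.all((self.mu > 0) & (self.mu < 1))
            and np.all((nu > 0) & (nu < 1))
            and self.sigma_mu > 0
            and self.sigma_delta > 0
            and self.kappa > 0
            and np.all(np.isfinite(self.mu))
            and np.all(np.isfinite(self.delta))
        )


def log_posterior(params: SSMParams, data: SSMData) -> float:
    """Log posterior on the constrained scale (flat priors over the support).

    Sum of the Normal transition terms for mu, the Cauchy transition terms
    for delta (both over t = 2..T), and the Beta-proportion observation
    terms for every replicate in both groups. ``-inf`` on support
    violations.
    """
    if params.mu.shape[0] != data.T:
        raise ValueError("parameter length does not match the data")
    if not params.in_support():
        return -np.inf
    mu, delta = params.mu, params.delta
    nu = mu + delta
    lp = 0.0
    u = np.diff(mu)
    lp += np.sum(
        -0.5 * np.log(2.0 * np.pi)
        - np.log(params.sigma_mu)
        - u * u / (2.0 * params.sigma_mu**2)
    )
    lp += np.sum(cauchy_logpdf(delta[1:], delta[:-1], params.sigma_delta))
    for t in range(data.T):
        if data.control[t].size:
            lp += np.sum(beta_proportion_logpdf(data.control[t], mu[t], params.kappa))
        if data.experimental[t].size:
            lp += np.sum(
                beta_proportion_logpdf(data.experimental[t], nu[t], params.kappa)
            )
    return float(lp)


# ---------------------------------------------------------------------------
# unconstrained target with analytic gradient
# ---------------------------------------------------------------------------


class _Target:
    """Unconstrained log target with analytic gradient.

    Parameterization: ``mu = sigmoid(a)`` (centered random walk); the
    difference path is non-centered to avoid the random-walk funnel —
    ``delta[t] = delta1 + sigma_delta * cumsum(tan(pi*(u_s - 1/2)))`` with
    ``u_s = sigmoid(utilde_s)``, so that standardized Cauchy increments
    become logistic-distributed coordinates with bounded geometry. Scales
    and kappa live on the log scale. Log Jacobians of all transforms are
    added, making the implied priors uniform over the constrained supports;
    the constraint ``mu + delta in (0,1)`` is enforced by returning -inf
    outside it. Sufficient statistics make each evaluation O(T).

    Layout of z: ``[a (T), delta1, utilde (T-1), lsm, lsd, lk]``.
    """

    def __init__(self, data: SSMData):
        self.T = data.T
        self.nc = np.array([v.size for v in data.control], dtype=float)
        self.ne = np.array([v.size for v in data.experimental], dtype=float)
        self.slc = np.array([np.sum(np.log(v)) for v in data.control])
        self.sl1c = np.array([np.sum(np.log1p(-v)) for v in data.control])
        self.sle = np.array([np.sum(np.log(v)) for v in data.experimental])
        self.sl1e = np.array([np.sum(np.log1p(-v)) for v in data.experimental])
        self.dim = 2 * self.T + 3

    def unpack(self, z: np.ndarray):
        T = self.T
        a = z[:T]
        delta1 = z[T]
        ut = z[T + 1 : 2 * T]
        lsm, lsd, lk = z[2 * T], z[2 * T + 1], z[2 * T + 2]
        return a, delta1, ut, lsm, lsd, lk

    def _states(self, z: np.ndarray):
        a, delta1, ut, lsm, lsd, lk = self.unpack(z)
        mu = expit(a)
        u = expit(ut)
        c = np.tan(np.pi * (u - 0.5))
        csum = np.concatenate([[0.0], np.cumsum(c)])
        delta = delta1 + np.exp(lsd) * csum
        return mu, delta, u, c, csum, lsm, lsd, lk

    def to_params(self, z: np.ndarray) -> SSMParams:
        mu, delta, _, _, _, lsm, lsd, lk = self._states(z)
        return SSMParams(mu, delta, np.exp(lsm), np.exp(lsd), np.exp(lk))

    def logp_grad(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        with np.errstate(all="ignore"):
            return self._logp_grad(z)

    def _logp_grad(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        T = self.T
        mu, delta, u, c, csum, lsm, lsd, lk = self._states(z)
        nu = mu + delta
        sm, sd, k = np.exp(lsm), np.exp(lsd), np.exp(lk)

        if np.any((nu <= 0) | (nu >= 1)) or not np.all(np.isfinite(nu)):
            return -np.inf, np.zeros(self.dim)

        jmu = mu * (1.0 - mu)
        ju = u * (1.0 - u)
        dmu_steps = np.diff(mu)

        # mu random-walk transitions (centered)
        lp = np.sum(
            -0.5 * np.log(2 * np.pi) - lsm - dmu_steps**2 / (2 * sm * sm)
        )
        # standardized Cauchy increments expressed through logistic coords:
        # the density contribution reduces to the logistic log Jacobian
        lp += np.sum(np.log(ju))

        # observation terms via sufficient statistics
        amc, bmc = mu * k, (1.0 - mu) * k
        ane, bne = nu * k, (1.0 - nu) * k
        lbc = gammaln(amc) + gammaln(bmc) - gammaln(k)
        lbe = gammaln(ane) + gammaln(bne) - gammaln(k)
        lp += np.sum(-self.nc * lbc + (amc - 1) * self.slc + (bmc - 1) * self.sl1c)
        lp += np.sum(-self.ne * lbe + (ane - 1) * self.sle + (bne - 1) * self.sl1e)

        # log Jacobians for mu and the log-scale parameters
        lp += np.sum(np.log(jmu)) + lsm + lsd + lk

        # --- gradients ---
        gN = np.zeros(T)
        gN[1:] += -dmu_steps / (sm * sm)
        gN[:-1] += dmu_steps / (sm * sm)

        psi_amc, psi_bmc = digamma(amc), digamma(bmc)
        psi_ane, psi_bne = digamma(ane), digamma(bne)
        gobs_c = k * (self.nc * (psi_bmc - psi_amc) + self.slc - self.sl1c)
        gobs_e = k * (self.ne * (psi_bne - psi_ane) + self.sle - self.sl1e)

        da = jmu * (gN + gobs_c + gobs_e) + (1.0 - 2.0 * mu)
        ddelta1 = np.sum(gobs_e)
        # reverse cumulative sum: increment s feeds all t >= s
        rev = np.cumsum(gobs_e[::-1])[::-1]
        dut = sd * np.pi * ju * (1.0 + c * c) * rev[1:] + (1.0 - 2.0 * u)

        dlsm = np.sum(-1.0 + dmu_steps**2 / (sm * sm)) + 1.0
        dlsd = sd * np.sum(gobs_e * csum) + 1.0

        psik = digamma(k)
        dk_c = self.nc * (psik - mu * psi_amc - (1 - mu) * psi_bmc)
        dk_c += mu * self.slc + (1 - mu) * self.sl1c
        dk_e = self.ne * (psik - nu * psi_ane - (1 - nu) * psi_bne)
        dk_e += nu * self.sle + (1 - nu) * self.sl1e
        dlk = k * (np.sum(dk_c) + np.sum(dk_e)) + 1.0

        grad = np.concatenate([da, [ddelta1], dut, [dlsm, dlsd, dlk]])
        return float(lp), grad


def _initial_point(data: SSMData, target: _Target, rng: np.random.Generator) -> np.ndarray:
    """Data-driven start: logits of clipped per-t group means plus jitter."""
    mc = np.array([v.mean() if v.size else np.nan for v in data.control])
    me = np.array([v.mean() if v.size else np.nan for v in data.experimental])
    mc = pd.Series(mc).ffill().bfill().fillna(0.5).to_numpy()
    me = pd.Series(me).ffill().bfill().fillna(0.5).to_numpy()
    mc = np.clip(mc, 0.02, 0.98)
    me = np.clip(me, 0.02, 0.98)
    pooled = np.concatenate([np.concatenate(data.control), np.concatenate(data.experimental)])
    var = max(pooled.var(), 1e-4)
    m = pooled.mean()
    kappa0 = np.clip(m * (1 - m) / var - 1.0, 5.0, 500.0)
    delta1 = float(np.clip(me[0] - mc[0], -0.5, 0.5))
    z = np.concatenate(
        [
            logit(mc) + rng.normal(0.0, 0.1, data.T),
            [delta1 + rng.normal(0.0, 0.02)],
            rng.normal(0.0, 0.1, data.T - 1),  # utilde: increments near zero
            np.array([np.log(0.05), np.log(0.02), np.log(kappa0)])
            + rng.normal(0.0, 0.1, 3),
        ]
    )
    return z


# ---------------------------------------------------------------------------
# NUTS sampler
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SamplerSettings:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    max_treedepth: int = 8
    target_accept: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.chains, self.warmup, self.draws) < 1:
            raise ValueError("chains, warmup, and draws must be positive")


def _leapfrog(z, r, eps, grad, target, inv_mass):
    r = r + 0.5 * eps * grad
    z = z + eps * inv_mass * r
    lp, grad = target.logp_grad(z)
    r = r + 0.5 * eps * grad
    return z, r, lp, grad


def _hamiltonian(lp, r, inv_mass):
    return lp - 0.5 * np.sum(inv_mass * r * r)


_DELTA_MAX = 1000.0


def _build_tree(z, r, grad, logu, v, depth, eps, target, inv_mass, h0, rng):
    if depth == 0:
        z1, r1, lp1, grad1 = _leapfrog(z, r, v * eps, grad, target, inv_mass)
        h1 = _hamiltonian(lp1, r1, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        n1 = int(logu <= h1)
        s1 = int(logu < h1 + _DELTA_MAX)
        alpha = min(1.0, np.exp(min(h1 - h0, 0.0)))
        return z1, r1, grad1, z1, r1, grad1, z1, lp1, n1, s1, alpha, 1
    (
        zm, rm, gm, zp, rp, gp, zq, lpq, n1, s1, a1, na1,
    ) = _build_tree(z, r, grad, logu, v, depth - 1, eps, target, inv_mass, h0, rng)
    if s1:
        if v == -1:
            zm, rm, gm, _, _, _, zq2, lpq2, n2, s2, a2, na2 = _build_tree(
                zm, rm, gm, logu, v, depth - 1, eps, target, inv_mass, h0, rng
            )
        else:
            _, _, _, zp, rp, gp, zq2, lpq2, n2, s2, a2, na2 = _build_tree(
                zp, rp, gp, logu, v, depth - 1, eps, target, inv_mass, h0, rng
            )
        if n1 + n2 > 0 and rng.random() < n2 / (n1 + n2):
            zq, lpq = zq2, lpq2
        dz = zp - zm
        s1 = (
            s2
            * int(np.dot(dz, inv_mass * rm) >= 0)
            * int(np.dot(dz, inv_mass * rp) >= 0)
        )
        n1 += n2
        a1 += a2
        na1 += na2
    return zm, rm, gm, zp, rp, gp, zq, lpq, n1, s1, a1, na1


def _draw_momentum(rng, inv_mass):
    r = rng.standard_normal(inv_mass.size)
    active = inv_mass > 0
    r[active] /= np.sqrt(inv_mass[active])
    r[~active] = 0.0
    return r


def _find_reasonable_epsilon(z, target, inv_mass, rng):
    eps = 1.0
    lp, grad = target.logp_grad(z)
    r = _draw_momentum(rng, inv_mass)
    h0 = _hamiltonian(lp, r, inv_mass)
    z1, r1, lp1, _ = _leapfrog(z, r, eps, grad, target, inv_mass)
    h1 = _hamiltonian(lp1, r1, inv_mass)
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if h1 - h0 > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        z1, r1, lp1, _ = _leapfrog(z, r, eps, grad, target, inv_mass)
        h1 = _hamiltonian(lp1, r1, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) <= direction * np.log(0.5):
            break
    return max(eps, 1e-8)


class _DualAveraging:
    """Nesterov dual averaging of the log step size."""

    def __init__(self, eps0: float, target: float):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.hbar = 0.0
        self.m = 0
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75

    def update(self, accept_prob: float) -> float:
        self.m += 1
        frac = 1.0 / (self.m + self.t0)
        self.hbar = (1 - frac) * self.hbar + frac * (self.target - accept_prob)
        self.log_eps = self.mu - np.sqrt(self.m) / self.gamma * self.hbar
        eta = self.m**-self.kappa
        self.log_eps_bar = eta * self.log_eps + (1 - eta) * self.log_eps_bar
        return float(np.exp(self.log_eps))

    @property
    def adapted_eps(self) -> float:
        return float(np.exp(self.log_eps_bar)) if self.m else float(np.exp(self.log_eps))


def _adaptation_schedule(warmup: int, init_buffer=75, term_buffer=50, base_window=25):
    """Ends of the expanding mass-matrix windows (Stan-style schedule)."""
    if warmup < init_buffer + term_buffer + base_window:
        init_buffer = max(1, int(0.15 * warmup))
        term_buffer = max(1, int(0.1 * warmup))
        base_window = max(1, warmup - init_buffer - term_buffer)
    ends = []
    start = init_buffer
    size = base_window
    while start + size < warmup - term_buffer:
        ends.append(start + size)
        start += size
        size *= 2
    ends.append(warmup - term_buffer)
    return ends


def _nuts_chain(target: _Target, z0, settings: SamplerSettings, rng):
    """One NUTS chain: warmup with step-size/metric adaptation, then draws."""
    dim = z0.size
    inv_mass = np.ones(dim)
    z = z0.copy()
    lp, grad = target.logp_grad(z)
    if not np.isfinite(lp):
        raise RuntimeError("non-finite posterior at initialization")

    eps = _find_reasonable_epsilon(z, target, inv_mass, rng)
    da = _DualAveraging(eps, settings.target_accept)

    warm = settings.warmup
    window_ends = _adaptation_schedule(warm)
    win_sum = np.zeros(dim)
    win_sumsq = np.zeros(dim)
    win_n = 0

    samples = np.empty((settings.draws, dim))
    accept_stats = []
    for m in range(warm + settings.draws):
        r0 = _draw_momentum(rng, inv_mass)
        h0 = _hamiltonian(lp, r0, inv_mass)
        logu = h0 - rng.exponential(1.0)
        zm = zp = z
        rm = rp = r0
        gm = gp = grad
        zq, lpq = z, lp
        n, s = 1, 1
        alpha, nalpha = 0.0, 1
        depth = 0
        while s and depth < settings.max_treedepth:
            v = -1 if rng.random() < 0.5 else 1
            if v == -1:
                zm, rm, gm, _, _, _, zq2, lpq2, n2, s2, alpha, nalpha = _build_tree(
                    zm, rm, gm, logu, v, depth, eps, target, inv_mass, h0, rng
                )
            else:
                _, _, _, zp, rp, gp, zq2, lpq2, n2, s2, alpha, nalpha = _build_tree(
                    zp, rp, gp, logu, v, depth, eps, target, inv_mass, h0, rng
                )
            if s2 and n2 > 0 and rng.random() < min(1.0, n2 / n):
                zq, lpq = zq2, lpq2
            n += n2
            dz = zp - zm
            s = (
                s2
                * int(np.dot(dz, inv_mass * rm) >= 0)
                * int(np.dot(dz, inv_mass * rp) >= 0)
            )
            depth += 1
        if not np.array_equal(zq, z):
            z, lp = zq, lpq
            _, grad = target.logp_grad(z)

        if m < warm:
            eps = da.update(alpha / max(nalpha, 1))
            win_sum += z
            win_sumsq += z * z
            win_n += 1
            if window_ends and m + 1 == window_ends[0]:
                window_ends.pop(0)
                if win_n >= 10:
                    var = win_sumsq / win_n - (win_sum / win_n) ** 2
                    inv_mass = np.maximum(
                        win_n / (win_n + 5.0) * var + 1e-3 * (5.0 / (win_n + 5.0)),
                        1e-10,
                    )
                    eps = _find_reasonable_epsilon(z, target, inv_mass, rng)
                    da = _DualAveraging(eps, settings.target_accept)
                win_sum[:] = 0.0
                win_sumsq[:] = 0.0
                win_n = 0
            if m == warm - 1:
                eps = da.adapted_eps
        else:
            samples[m - warm] = z
            accept_stats.append(alpha / max(nalpha, 1))
    return samples, float(np.mean(accept_stats))


@dataclass
class SSMPosterior:
    """Posterior draws with convergence diagnostics and band summaries."""

    mu: np.ndarray  # (chains, draws, T)
    delta: np.ndarray  # (chains, draws, T)
    sigma_mu: np.ndarray  # (chains, draws)
    sigma_delta: np.ndarray
    kappa: np.ndarray
    times_s: np.ndarray | None = None
    mean_accept: float = float("nan")
    diagnostics: pd.DataFrame | None = None
    converged: bool = True

    @property
    def n_draws(self) -> int:
        return self.mu.shape[0] * self.mu.shape[1]

    def flat(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])

    def draws_table(self) -> pd.DataFrame:
        T = self.mu.shape[2]
        cols = {}
        for t in range(T):
            cols[f"mu[{t + 1}]"] = self.flat("mu")[:, t]
            cols[f"delta[{t + 1}]"] = self.flat("delta")[:, t]
        cols["sigma_mu"] = self.flat("sigma_mu")
        cols["sigma_delta"] = self.flat("sigma_delta")
        cols["kappa"] = self.flat("kappa")
        return pd.DataFrame(cols)


def _diagnostics(posterior: SSMPosterior) -> pd.DataFrame:
    import arviz as az

    ds = az.from_dict(
        posterior={
            "mu": posterior.mu,
            "delta": posterior.delta,
            "sigma_mu": posterior.sigma_mu,
            "sigma_delta": posterior.sigma_delta,
            "kappa": posterior.kappa,
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(ds)
        ess = az.ess(ds)
    rows = []
    for name in ("mu", "delta", "sigma_mu", "sigma_delta", "kappa"):
        r = np.atleast_1d(rhat[name].values)
        e = np.atleast_1d(ess[name].values)
        for i, (ri, ei) in enumerate(zip(r, e)):
            label = name if r.size == 1 else f"{name}[{i + 1}]"
            rows.append({"parameter": label, "rhat": float(ri), "ess_bulk": float(ei)})
    return pd.DataFrame(rows)


def sample_posterior(
    data: SSMData,
    settings: SamplerSettings | None = None,
    rhat_threshold: float = 1.01,
    min_ess: float = 100.0,
    compute_diagnostics: bool = True,
) -> SSMPosterior:
    """Run NUTS over the state-space log posterior.

    Seed-reproducible per chain; sets ``converged=False`` (with a warning)
    if any reported parameter has split-R-hat above ``rhat_threshold`` or
    bulk ESS below ``min_ess``.
    """
    settings = settings or SamplerSettings()
    target = _Target(data)
    seeds = np.random.SeedSequence(settings.seed).spawn(settings.chains)
    mus, deltas, sms, sds, ks, accepts = [], [], [], [], [], []
    for seq in seeds:
        rng = np.random.default_rng(seq)
        z0 = _initial_point(data, target, rng)
        lp0, _ = target.logp_grad(z0)
        tries = 0
        while not np.isfinite(lp0) and tries < 20:
            z0 = _initial_point(data, target, rng)
            lp0, _ = target.logp_grad(z0)
            tries += 1
        if not np.isfinite(lp0):
            raise RuntimeError("could not find a finite starting point")
        samples, acc = _nuts_chain(target, z0, settings, rng)
        T = target.T
        mu = expit(samples[:, :T])
        sd = np.exp(samples[:, 2 * T + 1])
        c = np.tan(np.pi * (expit(samples[:, T + 1 : 2 * T]) - 0.5))
        csum = np.concatenate(
            [np.zeros((samples.shape[0], 1)), np.cumsum(c, axis=1)], axis=1
        )
        delta = samples[:, T][:, None] + sd[:, None] * csum
        mus.append(mu)
        deltas.append(delta)
        sms.append(np.exp(samples[:, 2 * T]))
        sds.append(sd)
        ks.append(np.exp(samples[:, 2 * T + 2]))
        accepts.append(acc)
    post = SSMPosterior(
        mu=np.asarray(mus),
        delta=np.asarray(deltas),
        sigma_mu=np.asarray(sms),
        sigma_delta=np.asarray(sds),
        kappa=np.asarray(ks),
        times_s=None if data.times_s is None else np.asarray(data.times_s),
        mean_accept=float(np.mean(accepts)),
    )
    if compute_diagnostics and settings.chains >= 2:
        diag = _diagnostics(post)
        post.diagnostics = diag
        post.converged = bool(
            (diag["rhat"] <= rhat_threshold).all() and (diag["ess_bulk"] >= min_ess).all()
        )
        if not post.converged:
            warnings.warn(
                "sampler convergence flags tripped (R-hat or ESS); "
                "inspect posterior.diagnostics",
                UserWarning,
                stacklevel=2,
            )
    return post


def summarize(posterior, times_s: np.ndarray | None = None) -> pd.DataFrame:
    """Per-time-point medians and central 95% credible intervals.

    Accepts an :class:`SSMPosterior` or a mapping with ``mu``/``delta``
    draw arrays of shape ``(n_draws, T)``. The ``excludes_zero`` column
    flags time points whose delta interval does not contain 0 (the visual
    criterion for a group difference).
    """
    if isinstance(posterior, SSMPosterior):
        mu = posterior.flat("mu")
        delta = posterior.flat("delta")
        if times_s is None:
            times_s = posterior.times_s
    else:
        mu = np.atleast_2d(np.asarray(posterior["mu"], dtype=float))
        delta = np.atleast_2d(np.asarray(posterior["delta"], dtype=float))
    if mu.size == 0 or delta.size == 0:
        raise ValueError("empty posterior draws")
    q = (2.5, 50.0, 97.5)
    mu_lo, mu_med, mu_hi = np.percentile(mu, q, axis=0)
    d_lo, d_med, d_hi = np.percentile(delta, q, axis=0)
    T = mu.shape[1]
    out = pd.DataFrame(
        {
            "t": np.arange(1, T + 1),
            "time_s": times_s if times_s is not None else np.arange(1, T + 1),
            "mu_med": mu_med,
            "mu_lo": mu_lo,
            "mu_hi": mu_hi,
            "delta_med": d_med,
            "delta_lo": d_lo,
            "delta_hi": d_hi,
        }
    )
    out["excludes_zero"] = (out["delta_lo"] > 0) | (out["delta_hi"] < 0)
    return out
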