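"""Maximum-likelihood fitting of isolation (Iso), isolation-with-migration
(IM) and isolation-with-initial-migration (IIM) models from per-locus pairwise
nucleotide difference counts.

Model and units
---------------
Two populations split from a common ancestor at time ``t0`` (times increase
into the past).  Under IIM they exchange migrants from the split until time
``t1 <= t0``; under IM gene flow continues to the present (``t1 = 0``); under
Iso there is none (``t1 = t0``).  A sampled pair of sequences is one of three
comparison classes: both from population 1, both from population 2, or one
from each.

Time is measured in mutational units: a pair whose lineages coalesce at time
``t`` carries ``s ~ Poisson(r t)`` differences, where ``r`` is the locus's
relative mutation rate (unit mean across loci).  A deme with diversity
parameter ``theta`` then coalesces a pair at rate ``1/theta``, so ``theta`` is
the expected pairwise diversity of that deme.  Migration rates ``M1, M2`` are
per coalescent unit of the reference population (``theta1``), i.e. rate
``M/theta1`` on the mutational-time scale; ``M1`` is the backwards rate at
which a lineage sampled in population 1 traces its ancestry into population 2.

The pairwise-difference pmf is computed epoch-wise from the lineage process
over the states {both-in-1, both-in-2, split}: closed-form exponential pieces
during isolation, an eigendecomposed matrix exponential during the migration
epoch integrated by adaptive Gauss-Legendre panels, and a Gauss-Laguerre rule
for the exponential ancestral tail.  The Iso between-class pmf has an
independent Poisson(+)Geometric closed form that is kept as a validation
oracle, never used by the fitting path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special, stats
from scipy.stats import qmc

log = logging.getLogger("ancinv")

MODELS = ("iso", "im", "iim")
CLASSES = ("within_pop1", "within_pop2", "between")
_START_STATE = {"within_pop1": 0, "within_pop2": 1, "between": 2}


@dataclass(frozen=True)
class ModelParams:
    """Parameter vector for one of the three divergence models."""

    model: str
    theta1: float
    theta2: float
    theta_anc: float
    t0: float
    t1: float = 0.0
    m1: float = 0.0
    m2: float = 0.0

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if min(self.theta1, self.theta2, self.theta_anc) <= 0:
            raise ValueError("all theta must be > 0")
        if self.t0 < 0 or not (0 <= self.t1 <= self.t0 + 1e-12):
            raise ValueError("require 0 <= t1 <= t0")
        if min(self.m1, self.m2) < 0:
            raise ValueError("migration rates must be >= 0")
        if self.model == "iso" and (self.m1 or self.m2):
            raise ValueError("Iso forces M1 = M2 = 0")
        if self.model == "im" and self.t1 != 0:
            raise ValueError("IM forces t1 = 0")

    @classmethod
    def iso(cls, theta1, theta2, theta_anc, t0):
        return cls("iso", theta1, theta2, theta_anc, t0, t1=t0)

    @classmethod
    def im(cls, theta1, theta2, theta_anc, t0, m1, m2):
        return cls("im", theta1, theta2, theta_anc, t0, t1=0.0, m1=m1, m2=m2)

    @classmethod
    def iim(cls, theta1, theta2, theta_anc, t0, t1, m1, m2):
        return cls("iim", theta1, theta2, theta_anc, t0, t1=t1, m1=m1, m2=m2)

    def free_names(self):
        return {
            "iso": ("theta1", "theta2", "theta_anc", "t0"),
            "im": ("theta1", "theta2", "theta_anc", "t0", "m1", "m2"),
            "iim": ("theta1", "theta2", "theta_anc", "t0", "t1", "m1", "m2"),
        }[self.model]

    def as_vector(self):
        return np.array([getattr(self, n) for n in self.free_names()])


def n_free_params(model):
    return {"iso": 4, "im": 6, "iim": 7}[model]


# ---------------------------------------------------------------------------
# coalescence-time density


class PairCoalDensity:
    """Coalescence-time density of one sampled pair, in mutational units.

    Epochs backwards in time: [0, t1) isolated demes; [t1, t0) demes coupled
    by migration; [t0, inf) single ancestral deme.  Evaluated via the 3-state
    transient lineage process {both-in-1, both-in-2, split}.
    """

    def __init__(self, params, cls):
        if cls not in CLASSES:
            raise ValueError(f"class must be one of {CLASSES}")
        p = params
        self.params = p
        self.cls = cls
        self.lam_iso = np.array([1.0 / p.theta1, 1.0 / p.theta2, 0.0])
        e = np.zeros(3)
        e[_START_STATE[cls]] = 1.0
        # isolation epoch [0, t1): states decay independently, no transitions
        self.p_t1 = e * np.exp(-self.lam_iso * p.t1)
        m1 = p.m1 / p.theta1
        m2 = p.m2 / p.theta1
        self.Q = np.array(
            [
                [-(2 * m1 + 1.0 / p.theta1), 0.0, 2 * m1],
                [0.0, -(2 * m2 + 1.0 / p.theta2), 2 * m2],
                [m2, m1, -(m1 + m2)],
            ]
        )
        self.absorb = np.array([1.0 / p.theta1, 1.0 / p.theta2, 0.0])
        self._use_eig = True
        if p.t0 > p.t1:
            try:
                w, V = linalg.eig(self.Q)
                Vinv = linalg.inv(V)
                if np.linalg.cond(V) > 1e10:
                    raise linalg.LinAlgError("ill-conditioned eigenbasis")
                self._w, self._V, self._c = w, V, self.p_t1 @ V
                self._Vinv = Vinv
            except linalg.LinAlgError:
                self._use_eig = False
        self.p_t0 = self._migration_state(p.t0 - p.t1)[0] if p.t0 > p.t1 else self.p_t1
        self.survival_t0 = float(self.p_t0.sum().real)

    def _migration_state(self, u):
        """State distributions (n, 3) after times ``u`` inside the migration epoch."""
        u = np.atleast_1d(np.asarray(u, float))
        if self._use_eig:
            out = np.real((self._c[None, :] * np.exp(self._w[None, :] * u[:, None])) @ self._Vinv)
        else:
            out = np.array([self.p_t1 @ linalg.expm(self.Q * ui) for ui in u])
        return np.clip(out, 0.0, None)

    def state_at(self, t):
        t = float(t)
        p = self.params
        if t <= p.t1:
            e = np.zeros(3)
            e[_START_STATE[self.cls]] = 1.0
            return e * np.exp(-self.lam_iso * t)
        if t <= p.t0:
            return self._migration_state(t - p.t1)[0]
        return self.p_t0 * np.exp(-(t - p.t0) / p.theta_anc)

    def __call__(self, t):
        """Density f(t); vectorized over t; integrates to 1."""
        t = np.asarray(t, float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        p = self.params
        out = np.zeros_like(t)
        e = np.zeros(3)
        e[_START_STATE[self.cls]] = 1.0
        a = t < p.t1
        if a.any():
            out[a] = np.sum(e * self.lam_iso * np.exp(-np.outer(t[a], self.lam_iso)), axis=1)
        b = (t >= p.t1) & (t < p.t0)
        if b.any():
            out[b] = self._migration_state(t[b] - p.t1) @ self.absorb
        c = t >= p.t0
        if c.any():
            out[c] = self.survival_t0 / p.theta_anc * np.exp(-(t[c] - p.t0) / p.theta_anc)
        return float(out[0]) if scalar else out


def pair_coal_density(params, cls):
    """Factory matching the operation contract: returns the density callable."""
    return PairCoalDensity(params, cls)


# ---------------------------------------------------------------------------
# pairwise-difference pmf


def _pois_matrix(s, rt):
    """exp(s log(rt) - rt - log s!) for s (n,) against node products rt (n, k)."""
    s = s[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = s * np.log(rt) - rt - special.gammaln(s + 1)
    logp = np.where((rt == 0) & (s == 0), 0.0, logp)
    return np.exp(logp)


def log_pmf(params, cls, s, r, gl_order=12, base_panels=8, tol=1e-10, max_panels=256):
    """log P(s differences) for loci with relative rates ``r``.

    Vectorized over loci.  The migration-epoch integral is refined by doubling
    the Gauss-Legendre panel count until the quadrature mass matches the
    exactly known absorbed probability to ``tol`` (non-convergence raises).
    """
    s = np.atleast_1d(np.asarray(s))
    r = np.broadcast_to(np.asarray(r, float), s.shape).astype(float)
    if (s < 0).any() or (r <= 0).any():
        raise ValueError("require s >= 0 and r > 0")
    dens = PairCoalDensity(params, cls)
    p = params
    total = np.zeros(len(s))

    # isolation epoch: closed exponential piece for the starting within state
    k = _START_STATE[cls]
    lam = dens.lam_iso[k]
    if p.t1 > 0 and lam > 0:
        rate = r + lam
        total += (
            lam
            * np.exp(s * np.log(r) - (s + 1) * np.log(rate))
            * special.gammainc(s + 1, rate * p.t1)
        )

    # migration epoch: adaptive Gauss-Legendre panels on [t1, t0)
    if p.t0 > p.t1:
        absorbed_exact = float(dens.p_t1.sum() - dens.survival_t0)
        span = p.t0 - p.t1
        panels = base_panels
        xg, wg = np.polynomial.legendre.leggauss(gl_order)
        while True:
            edges = np.linspace(0.0, span, panels + 1)
            half = 0.5 * np.diff(edges)
            mid = 0.5 * (edges[:-1] + edges[1:])
            nodes = (mid[:, None] + half[:, None] * xg[None, :]).ravel()
            weights = (half[:, None] * wg[None, :]).ravel()
            fvals = dens(p.t1 + nodes)
            W = weights * fvals
            if abs(W.sum() - absorbed_exact) <= tol * max(1.0, absorbed_exact):
                break
            if panels >= max_panels:
                raise RuntimeError(
                    f"quadrature did not converge: mass {W.sum():.3e} vs {absorbed_exact:.3e}"
                )
            panels *= 2
        t_nodes = p.t1 + nodes
        total += _pois_matrix(s, r[:, None] * t_nodes[None, :]) @ W

    # ancestral tail: Gauss-Laguerre on the exponential epoch beyond t0
    S0 = dens.survival_t0
    if S0 > 0:
        smax = int(s.max())
        n_lag = min(max(40, smax // 2 + 10), 120)
        x, wl = special.roots_laguerre(n_lag)
        rho = r + 1.0 / p.theta_anc
        T = p.t0 + x[None, :] / rho[:, None]
        with np.errstate(divide="ignore"):
            logterm = (
                s[:, None] * np.log(r[:, None] * T)
                - special.gammaln(s + 1)[:, None]
                + np.log(wl)[None, :]
            )
        logterm = np.where((T == 0) & (s[:, None] == 0), np.log(wl)[None, :], logterm)
        tail = (S0 / (p.theta_anc * rho)) * np.exp(-r * p.t0 + special.logsumexp(logterm, axis=1))
        total += tail

    return np.log(np.clip(total, 1e-300, None))


def pmf(params, cls, s, r=1.0, **kw):
    s = np.atleast_1d(np.asarray(s))
    return np.exp(log_pmf(params, cls, s, np.broadcast_to(r, s.shape), **kw))


def iso_between_pmf_closed(s, r, t0, theta_anc):
    """Validation oracle: Iso between-class pmf as Poisson(r t0) convolved
    with Geometric(mean r theta_anc), via the regularized incomplete gamma."""
    s = np.atleast_1d(np.asarray(s, float))
    m = r * theta_anc
    q = m / (1.0 + m)
    lam = r * t0
    if lam == 0:
        return (1.0 / (1.0 + m)) * q**s
    x = lam / q
    return (1.0 / (1.0 + m)) * np.exp(s * np.log(q) + x - lam) * special.gammaincc(s + 1, x)


# ---------------------------------------------------------------------------
# locus data structures


@dataclass(frozen=True)
class Locus:
    id: str
    cls: str
    s: int
    r: float = 1.0
    length: int = 500

    def __post_init__(self):
        if self.cls not in CLASSES:
            raise ValueError(f"class must be one of {CLASSES}")
        if self.s < 0 or self.r <= 0:
            raise ValueError("require s >= 0 and r > 0")


def loci_frame(loci):
    if isinstance(loci, pd.DataFrame):
        return loci
    return pd.DataFrame([l.__dict__ for l in loci])


def locus_loglik(locus, params):
    """Log-probability of one locus's difference count under ``params``."""
    return float(log_pmf(params, locus.cls, np.array([locus.s]), np.array([locus.r]))[0])


def loglik(params, loci):
    """Summed log-likelihood over a locus table (columns cls, s, r)."""
    df = loci_frame(loci)
    total = 0.0
    for cls, sub in df.groupby("cls"):
        total += log_pmf(params, cls, sub["s"].to_numpy(), sub["r"].to_numpy()).sum()
    return float(total)


def relative_rates(dxy_out):
    """Per-locus relative mutation rates from outgroup divergence: r_i =
    d_i / mean(d).  Zero-divergence loci get the floor 1e-3 and are flagged."""
    d = np.asarray(dxy_out, float)
    if (d < 0).any():
        raise ValueError("outgroup divergences must be >= 0")
    mean = d.mean()
    if mean == 0:
        raise ValueError("all outgroup divergences are zero")
    r = d / mean
    floored = r <= 0
    if floored.any():
        log.warning("relative_rates: %d loci floored to r = 1e-3", int(floored.sum()))
        r = np.where(floored, 1e-3, r)
    return r


def sample_loci(intergenic, locus_len=500, min_gap=10_000, n_sets=3, seed=0, max_attempts=None):
    """Randomly place non-overlapping loci inside intergenic intervals.

    Every pair of loci is separated by at least ``min_gap`` between nearest
    ends; accepted loci are randomly split into ``n_sets`` near-equal disjoint
    sets.  Deterministic given ``seed``.  Returns a DataFrame with columns
    chrom, start, end, set.
    """
    iv = intergenic.df[intergenic.df["end"] - intergenic.df["start"] >= locus_len]
    if len(iv) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "set"])
    rng = np.random.default_rng(seed)
    lengths = (iv["end"] - iv["start"] - locus_len + 1).to_numpy(float)
    capacity = int(np.ceil((iv["end"] - iv["start"]).sum() / (locus_len + min_gap))) + len(iv)
    attempts = max_attempts or 20 * capacity
    placed = {}  # chrom -> sorted list of (start, end)
    import bisect

    for _ in range(attempts):
        row = iv.iloc[rng.choice(len(iv), p=lengths / lengths.sum())]
        start = int(rng.integers(row["start"], row["end"] - locus_len + 1))
        end = start + locus_len
        lst = placed.setdefault(row["chrom"], [])
        i = bisect.bisect_left(lst, (start, end))
        ok = True
        if i > 0 and start - lst[i - 1][1] < min_gap:
            ok = False
        if i < len(lst) and lst[i][0] - end < min_gap:
            ok = False
        if ok:
            lst.insert(i, (start, end))
    rows = [
        {"chrom": chrom, "start": s, "end": e}
        for chrom, lst in placed.items()
        for s, e in lst
    ]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"]).sort_values(["chrom", "start"])
    order = rng.permutation(len(df))
    sets = np.empty(len(df), int)
    sets[order] = np.arange(len(df)) % n_sets
    df["set"] = sets
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# fitting


_LOG_BOUND = (-7.0, 6.0)
_Z_MIG_BOUND = (-25.0, 6.0)
_Z_PHI_BOUND = (-10.0, 10.0)
_PIN_TOL = 1e-5


def _softplus(z):
    return np.logaddexp(0.0, z)


def _softplus_inv(m):
    m = max(m, 1e-10)
    return m + np.log(-np.expm1(-m)) if m > 1e-8 else np.log(np.expm1(m))


def _build_params(model, x):
    th1, th2, tha, t0 = np.exp(x[0]), np.exp(x[1]), np.exp(x[2]), np.exp(x[3])
    if model == "iso":
        return ModelParams.iso(th1, th2, tha, t0)
    if model == "im":
        return ModelParams.im(th1, th2, tha, t0, _softplus(x[4]), _softplus(x[5]))
    phi = special.expit(x[4])
    return ModelParams.iim(th1, th2, tha, t0, phi * t0, _softplus(x[5]), _softplus(x[6]))


def _transform_bounds(model):
    b = [_LOG_BOUND] * 4
    if model == "im":
        b += [_Z_MIG_BOUND] * 2
    elif model == "iim":
        b += [_Z_PHI_BOUND] + [_Z_MIG_BOUND] * 2
    return b


@dataclass
class FitResult:
    model: str
    params: ModelParams
    lnl: float
    ci: dict
    pinned: tuple
    converged: bool
    n_restarts: int
    message: str = ""

    def summary(self):
        lines = [f"{self.model.upper()} fit: lnL = {self.lnl:.4f} (restarts={self.n_restarts})"]
        for name in self.params.free_names():
            v = getattr(self.params, name)
            if name in self.pinned:
                lines.append(f"  {name:10s} = {v:.5g}  [boundary; CI suppressed]")
            elif self.ci.get(name) is not None:
                lo, hi = self.ci[name]
                lines.append(f"  {name:10s} = {v:.5g}  (95% CI {lo:.5g} .. {hi:.5g})")
            else:
                lines.append(f"  {name:10s} = {v:.5g}  [CI unavailable]")
        return "\n".join(lines)


def _moment_start(df, model):
    """Method-of-moments center for the restart cloud."""
    def cls_mean(cls, default):
        sub = df[df["cls"] == cls]
        if len(sub) == 0:
            return default
        return max(float((sub["s"] / sub["r"]).mean()), 0.05)

    th1 = cls_mean("within_pop1", 1.0)
    th2 = cls_mean("within_pop2", 1.0)
    between = cls_mean("between", th1 + 1.0)
    tha = 0.5 * (th1 + th2)
    t0 = max(between - tha, 0.1)
    x = [np.log(th1), np.log(th2), np.log(tha), np.log(t0)]
    if model == "im":
        x += [_softplus_inv(0.2)] * 2
    elif model == "iim":
        x += [0.0, _softplus_inv(0.2), _softplus_inv(0.2)]
    return np.array(x)


def fit_model(loci, model, n_restarts=5, seed=0, bounds=None, maxiter=400):
    """Maximize the likelihood by bounded quasi-Newton from Latin-hypercube
    starts around a method-of-moments center; Wald 95% CIs from the inverted
    finite-difference Hessian at the optimum."""
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    df = loci_frame(loci)
    present = set(df["cls"])
    if not present:
        raise ValueError("no loci provided")
    grouped = [(cls, sub["s"].to_numpy(), sub["r"].to_numpy()) for cls, sub in df.groupby("cls")]

    def nll(x):
        try:
            params = _build_params(model, x)
            return -sum(log_pmf(params, cls, s, r).sum() for cls, s, r in grouped)
        except (ValueError, RuntimeError, FloatingPointError):
            return 1e12

    tb = bounds or _transform_bounds(model)
    center = _moment_start(df, model)
    ndim = len(center)
    sampler = qmc.LatinHypercube(d=ndim, seed=seed)
    jitter = sampler.random(n=max(n_restarts - 1, 0)) * 2.0 - 1.0
    starts = [center] + [np.clip(center + 1.2 * j, [b[0] for b in tb], [b[1] for b in tb]) for j in jitter]

    best = None
    for x0 in starts[:n_restarts]:
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=tb, options={"maxiter": maxiter})
        if best is None or res.fun < best.fun:
            best = res
    params = _build_params(model, best.x)
    lnl = -float(best.fun)

    names = params.free_names()
    v0 = params.as_vector()
    pinned = tuple(
        n
        for n, v in zip(names, v0)
        if (n in ("m1", "m2") and v < _PIN_TOL)
        or (n == "t1" and (v < _PIN_TOL * max(params.t0, 1.0) or v > (1 - _PIN_TOL) * params.t0))
    )
    ci = _wald_ci(model, names, v0, grouped, pinned)
    return FitResult(
        model=model,
        params=params,
        lnl=lnl,
        ci=ci,
        pinned=pinned,
        converged=bool(best.success),
        n_restarts=n_restarts,
        message=str(best.message),
    )


def _nll_natural(model, names, v, grouped):
    kw = dict(zip(names, v))
    try:
        if model == "iso":
            params = ModelParams.iso(kw["theta1"], kw["theta2"], kw["theta_anc"], kw["t0"])
        elif model == "im":
            params = ModelParams.im(kw["theta1"], kw["theta2"], kw["theta_anc"], kw["t0"], kw["m1"], kw["m2"])
        else:
            t1 = min(max(kw["t1"], 0.0), kw["t0"])
            params = ModelParams.iim(kw["theta1"], kw["theta2"], kw["theta_anc"], kw["t0"], t1, kw["m1"], kw["m2"])
        return -sum(log_pmf(params, cls, s, r).sum() for cls, s, r in grouped)
    except (ValueError, RuntimeError):
        return np.nan


def _wald_ci(model, names, v0, grouped, pinned, rel_step=1e-3):
    free = [i for i, n in enumerate(names) if n not in pinned]
    k = len(free)
    if k == 0:
        return {n: None for n in names}
    h = np.array([rel_step * max(abs(v0[i]), 1e-3) for i in free])
    H = np.full((k, k), np.nan)
    f0 = _nll_natural(model, names, v0, grouped)

    def f(dv):
        v = v0.copy()
        for idx, d in dv:
            v[idx] += d
        return _nll_natural(model, names, v, grouped)

    for a in range(k):
        ia = free[a]
        H[a, a] = (f([(ia, h[a])]) - 2 * f0 + f([(ia, -h[a])])) / h[a] ** 2
        for b in range(a + 1, k):
            ib = free[b]
            H[a, b] = H[b, a] = (
                f([(ia, h[a]), (ib, h[b])])
                - f([(ia, h[a]), (ib, -h[b])])
                - f([(ia, -h[a]), (ib, h[b])])
                + f([(ia, -h[a]), (ib, -h[b])])
            ) / (4 * h[a] * h[b])
    ci = {n: None for n in names}
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        for a, i in enumerate(free):
            if np.isfinite(se[a]) and se[a] > 0:
                ci[names[i]] = (float(v0[i] - 1.96 * se[a]), float(v0[i] + 1.96 * se[a]))
    except np.linalg.LinAlgError:
        log.warning("singular Hessian; Wald CIs unavailable")
    return ci


# ---------------------------------------------------------------------------
# model comparison


def scaled_lrt(lnl_null, lnl_alt, x=1.0, df=1):
    """Linkage-scaled likelihood-ratio test: 2(lnL_alt - lnL_null)/x against
    chi-square with ``df`` degrees of freedom.  ``x`` is the mean number of
    loci per dependence block (1 for independent loci)."""
    if x <= 0 or df < 1:
        raise ValueError("require x > 0 and df >= 1")
    slack = 1e-6 * max(1.0, abs(lnl_null))
    if lnl_alt < lnl_null - slack:
        raise ValueError(f"model nesting violated: lnL_alt {lnl_alt} < lnL_null {lnl_null}")
    stat = max(2.0 * (lnl_alt - lnl_null) / x, 0.0)
    return float(stat), float(stats.chi2.sf(stat, df))


def hierarchical_fit(partitioned_loci, model="iim", n_restarts=5, seed=0, **kw):
    """Free (per-partition) versus shared (single parameter vector) fits.

    Returns (per-partition FitResults, lnL_free, shared FitResult, lnL_shared,
    df) where df = (n_partitions - 1) x n_params for the scaled LRT.
    """
    names = list(partitioned_loci)
    if len(names) < 2:
        raise ValueError("need >= 2 partitions")
    for name in names:
        if len(loci_frame(partitioned_loci[name])) == 0:
            raise ValueError(f"partition {name!r} has no loci")
    free_fits = {}
    lnl_free = 0.0
    for i, name in enumerate(names):
        res = fit_model(partitioned_loci[name], model, n_restarts=n_restarts, seed=seed + i, **kw)
        free_fits[name] = res
        lnl_free += res.lnl
    pooled = pd.concat([loci_frame(partitioned_loci[n]) for n in names], ignore_index=True)
    shared = fit_model(pooled, model, n_restarts=n_restarts, seed=seed + len(names), **kw)
    df = (len(names) - 1) * n_free_params(model)
    return free_fits, float(lnl_free), shared, float(shared.lnl), df
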