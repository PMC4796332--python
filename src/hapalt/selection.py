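"""Locus- and deme-specific selection inference under Wright's island model,
plus genotype-altitude association tests.

Model
-----
Each deme ``i`` exchanges migrants with a common pool at scaled rate ``M``;
at locus ``j`` the derived allele has scaled selection coefficient
``sigma_ij = 2 * N_i * s_ij >= 0``.  The stationary distribution of the deme
allele frequency under the diffusion approximation with genic selection is

    pi(p) ∝ p^(M*pi_j - 1) * (1-p)^(M*(1-pi_j) - 1) * exp(sigma * p),

where ``pi_j`` is the migrant-pool derived-allele frequency.  Observed
derived-allele counts are binomial draws given the latent ``p_ij``.  A
hierarchical exponential prior ``sigma_ij ~ Exp(delta_j)`` shrinks selection
coefficients toward zero locus-wise; inference is by component-wise
Metropolis-within-Gibbs with pilot-run proposal adaptation.

The normalizing constant of the stationary density is
``B(a, b) * 1F1(a; a+b; sigma)`` with ``a = M*pi``, ``b = M*(1-pi)``
(Kummer's confluent hypergeometric function), evaluated in log space with a
large-argument asymptotic fallback.

Association
-----------
``altitude_association`` regresses residence altitude on genotype coded
additively (dosage 0/1/2), dominantly (any derived allele) or recessively
(two derived alleles), per locus, reporting two-sided t-test p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .datamodel import MISSING, GenotypePanel

P_VALUE_FLOOR = 1e-300

#: rate of the exponential independence proposal for sigma (mean 50)
_IND_RATE = 0.02


# ---------------------------------------------------------------------------
# fitness models


@dataclass(frozen=True)
class FitnessModel:
    """Genotype -> relative fitness map for a beneficial derived allele A.

    additive:  w(AA) = 1+w, w(Aa) = 1+w/2, w(aa) = 1
    dominant:  w(AA) = w(Aa) = 1+w,        w(aa) = 1
    recessive: w(AA) = 1+w, w(Aa) = w(aa) = 1
    """

    mode: str = "additive"
    w: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("additive", "dominant", "recessive"):
            raise ValueError(f"unknown fitness mode {self.mode!r}")
        if self.w < 0:
            raise ValueError("fitness advantage w must be >= 0")

    def genotype_fitness(self) -> tuple[float, float, float]:
        """(w_AA, w_Aa, w_aa)."""
        if self.mode == "additive":
            return 1.0 + self.w, 1.0 + self.w / 2.0, 1.0
        if self.mode == "dominant":
            return 1.0 + self.w, 1.0 + self.w, 1.0
        return 1.0 + self.w, 1.0, 1.0


# ---------------------------------------------------------------------------
# stationary density


def _log_hyp1f1(a, c, x):
    """log 1F1(a; c; x) for x >= 0, with asymptotic fallback for overflow:
    1F1(a;c;x) ~ Gamma(c)/Gamma(a) * e^x * x^(a-c) as x -> +inf."""
    a = np.asarray(a, dtype=float)
    c = np.asarray(c, dtype=float)
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore", invalid="ignore"):
        val = special.hyp1f1(a, c, x)
        out = np.where(val > 0, np.log(np.where(val > 0, val, 1.0)), -np.inf)
    bad = ~np.isfinite(out) | (x > 600.0)
    if np.any(bad):
        xs = np.where(x > 0, x, 1.0)
        asym = (
            special.gammaln(c)
            - special.gammaln(a)
            + x
            + (a - c) * np.log(xs)
        )
        out = np.where(bad, asym, out)
    return out


def log_normalizer(M, pi_tilde, sigma):
    """log of the stationary-density normalizing constant (vectorized)."""
    a = np.asarray(M) * np.asarray(pi_tilde)
    b = np.asarray(M) * (1.0 - np.asarray(pi_tilde))
    return special.betaln(a, b) + _log_hyp1f1(a, a + b, sigma)


def stationary_log_density(p, M, pi_tilde, sigma):
    """Normalized log density of the island-model stationary distribution.

    Valid for ``0 < p < 1``, ``M > 0``, ``0 < pi_tilde < 1``, ``sigma >= 0``.
    With ``sigma = 0`` this is exactly the Beta(M*pi_tilde, M*(1-pi_tilde))
    log density.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("p must lie strictly inside (0, 1)")
    if np.any(np.asarray(M) <= 0):
        raise ValueError("M must be > 0")
    pi_t = np.asarray(pi_tilde, dtype=float)
    if np.any(pi_t <= 0) or np.any(pi_t >= 1):
        raise ValueError("pi_tilde must lie strictly inside (0, 1)")
    if np.any(np.asarray(sigma) < 0):
        raise ValueError("sigma must be >= 0")
    a = np.asarray(M) * pi_t
    b = np.asarray(M) * (1.0 - pi_t)
    return (
        (a - 1.0) * np.log(p)
        + (b - 1.0) * np.log1p(-p)
        + np.asarray(sigma) * p
        - log_normalizer(M, pi_t, sigma)
    )


# ---------------------------------------------------------------------------
# MCMC


@dataclass
class McmcSettings:
    """Sampler schedule; the defaults follow the component-wise MCMC recipe
    of the emulated method (25 pilot runs of 1000 iterations, 25,000-step
    burn-in, samples every 25 steps)."""

    pilot_runs: int = 25
    pilot_len: int = 1000
    burn_in: int = 25000
    thin: int = 25
    n_samples: int = 1000
    seed: int = 0
    delta_rate: float = 0.01  # hyper-prior rate on the locus shrinkage rates
    m_bounds: tuple[float, float] = (0.1, 1000.0)
    fix_M: float | None = None
    fix_pi: np.ndarray | float | None = None
    fix_delta: np.ndarray | float | None = None
    target_accept: tuple[float, float] = (0.25, 0.45)


@dataclass
class SelectionFit:
    """Posterior summaries of scaled selection coefficients.

    ``summary`` rows: deme, locus_id, post_mean, post_median, ci_low, ci_high
    (95% equal-tailed credible interval), ess, accept_rate.
    """

    summary: pd.DataFrame
    sigma_samples: np.ndarray  # (n_samples, n_demes, n_loci)
    demes: list[str]
    locus_ids: list[str]
    diagnostics: dict
    settings: McmcSettings
    delta_samples: np.ndarray | None = None  # (n_samples, n_loci)
    M_samples: np.ndarray | None = None  # (n_samples,)

    def sigma_mean(self) -> pd.DataFrame:
        means = self.sigma_samples.mean(axis=0)
        return pd.DataFrame(means, index=self.demes, columns=self.locus_ids)

    def write(self, summary_path, trace_path=None) -> None:
        self.summary.to_csv(summary_path, sep="\t", index=False,
                            float_format="%.6g")
        if trace_path is not None:
            n, d, l = self.sigma_samples.shape
            flat = self.sigma_samples.reshape(n, d * l)
            cols = [f"{dm}:{lc}" for dm in self.demes for lc in self.locus_ids]
            pd.DataFrame(flat, columns=cols).to_csv(
                trace_path, sep="\t", index=False, float_format="%.6g"
            )


def effective_sample_size(x: np.ndarray) -> float:
    """Autocorrelation-based ESS (initial positive sequence truncation)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1))
    acf = acf / acf[0]
    s = 0.0
    for k in range(1, n // 2):
        if acf[k] + (acf[k + 1] if k + 1 < n else 0.0) < 0:
            break
        s += acf[k]
    ess = n / (1.0 + 2.0 * s)
    return float(min(max(ess, 1.0), n))


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _expit(x):
    return special.expit(x)


def fit_selection(
    derived: np.ndarray,
    totals: np.ndarray,
    demes: list[str] | None = None,
    locus_ids: list[str] | None = None,
    mcmc: McmcSettings | None = None,
) -> SelectionFit:
    """Fit per-deme, per-locus scaled selection coefficients.

    Parameters
    ----------
    derived, totals : arrays (n_demes, n_loci)
        Derived-allele counts and total sampled chromosomes per deme x locus.
    """
    mcmc = mcmc or McmcSettings()
    n = np.asarray(derived, dtype=float)
    N = np.asarray(totals, dtype=float)
    if n.shape != N.shape or n.ndim != 2:
        raise ValueError("derived and totals must be matching 2-D arrays")
    if n.shape[0] < 2:
        raise ValueError("at least two demes are required")
    if np.any(N <= 0) or np.any(n < 0) or np.any(n > N):
        raise ValueError("invalid allele counts")
    D, L = n.shape
    demes = demes or [f"deme{i}" for i in range(D)]
    locus_ids = locus_ids or [f"locus{j}" for j in range(L)]
    rng = np.random.default_rng(mcmc.seed)

    # state
    p = np.clip((n + 0.5) / (N + 1.0), 1e-4, 1 - 1e-4)
    pooled = np.clip(n.sum(axis=0) / N.sum(axis=0), 1e-3, 1 - 1e-3)
    pi = pooled.copy() if mcmc.fix_pi is None else np.broadcast_to(
        np.asarray(mcmc.fix_pi, dtype=float), (L,)).copy()
    M = 10.0 if mcmc.fix_M is None else float(mcmc.fix_M)
    # moment-matched start: the sigma at which the stationary mode equals the
    # observed frequency (0 where the deme sits at or below the pool mean);
    # starting near the mode avoids a slow ignition race against the
    # hierarchical shrinkage rate
    a0 = M * pi
    b0 = M * (1.0 - pi)
    sigma = np.clip((b0 - 1.0) / (1.0 - p) - (a0 - 1.0) / p, 0.5, 500.0)
    delta = ((1.0 + D) / (mcmc.delta_rate + sigma.sum(axis=0))
             if mcmc.fix_delta is None
             else np.broadcast_to(np.asarray(mcmc.fix_delta, dtype=float),
                                  (L,)).copy())

    # proposal scales
    s_p = np.full((D, L), 0.5)
    s_sig = np.full((D, L), 2.0)
    s_pi = np.full(L, 0.3)
    s_M = 0.3

    loglik_bin = lambda pp: n * np.log(pp) + (N - n) * np.log1p(-pp)

    def prior_terms(pp, sig, pi_v, M_v):
        a = M_v * pi_v
        b = M_v * (1.0 - pi_v)
        return ((a - 1.0) * np.log(pp) + (b - 1.0) * np.log1p(-pp)
                + sig * pp - log_normalizer(M_v, pi_v, sig))

    acc = {"p": 0.0, "sigma": 0.0, "pi": 0.0, "M": 0.0}
    tries = {"p": 0, "sigma": 0, "pi": 0, "M": 0}

    def sweep(n_iter: int, adapt_count: bool = False):
        nonlocal p, sigma, pi, M, delta
        acc_local = {k: np.zeros_like(v) for k, v in
                     {"p": p, "sigma": sigma, "pi": pi}.items()}
        acc_M = 0
        for _ in range(n_iter):
            # --- p update (elementwise logit random walk)
            z = _logit(p) + rng.normal(0.0, s_p)
            p_new = np.clip(_expit(z), 1e-12, 1 - 1e-12)
            a = M * pi
            b = M * (1.0 - pi)
            # normalizer independent of p; proposal Jacobian log(p(1-p))
            def p_target(pp):
                return (loglik_bin(pp)
                        + (a - 1.0) * np.log(pp)
                        + (b - 1.0) * np.log1p(-pp)
                        + sigma * pp
                        + np.log(pp) + np.log1p(-pp))
            log_r = p_target(p_new) - p_target(p)
            accept = np.log(rng.random((D, L))) < log_r
            p = np.where(accept, p_new, p)
            acc_local["p"] += accept

            # --- sigma update: reflected random walk, mixed with an
            # occasional long-tailed independence proposal so the chain can
            # jump between the sigma ~ 0 mode and a strong-selection mode
            # (the hierarchical shrinkage makes the joint (sigma, delta)
            # posterior bimodal when selection is strong)
            use_ind = rng.random((D, L)) < 0.2
            rw = np.abs(sigma + rng.normal(0.0, s_sig))
            ind = rng.exponential(1.0 / _IND_RATE, size=(D, L))
            sig_new = np.where(use_ind, ind, rw)
            dlog = (
                (sig_new - sigma) * p
                - (log_normalizer(M, pi, sig_new)
                   - log_normalizer(M, pi, sigma))
                - delta * (sig_new - sigma)
            )
            # Hastings correction for the independence component
            dlog = dlog + np.where(use_ind, _IND_RATE * (sig_new - sigma), 0.0)
            accept = np.log(rng.random((D, L))) < dlog
            sigma = np.where(accept, sig_new, sigma)
            acc_local["sigma"] += accept

            # --- delta Gibbs (Exp(delta) likelihood, Exp(delta_rate) hyper)
            if mcmc.fix_delta is None:
                delta = rng.gamma(shape=1.0 + D,
                                  scale=1.0 / (mcmc.delta_rate
                                               + sigma.sum(axis=0)))
                delta = np.clip(delta, 1e-8, None)

            # --- pi update (per locus, logit random walk)
            if mcmc.fix_pi is None:
                z = _logit(pi) + rng.normal(0.0, s_pi)
                pi_new = np.clip(_expit(z), 1e-12, 1 - 1e-12)

                def pi_target(pi_v):
                    return (prior_terms(p, sigma, pi_v, M).sum(axis=0)
                            + np.log(pi_v) + np.log1p(-pi_v))

                log_r = pi_target(pi_new) - pi_target(pi)
                accept = np.log(rng.random(L)) < log_r
                pi = np.where(accept, pi_new, pi)
                acc_local["pi"] += accept

            # --- M update (log random walk, log-uniform prior)
            if mcmc.fix_M is None:
                M_new = float(np.exp(np.log(M) + rng.normal(0.0, s_M)))
                lo, hi = mcmc.m_bounds
                if lo <= M_new <= hi:
                    log_r = (prior_terms(p, sigma, pi, M_new).sum()
                             - prior_terms(p, sigma, pi, M).sum())
                    if np.log(rng.random()) < log_r:
                        M = M_new
                        acc_M += 1
        if adapt_count:
            return acc_local, acc_M
        for k in acc_local:
            acc[k] += float(np.mean(acc_local[k]))
        acc["M"] += acc_M
        for k in tries:
            tries[k] += n_iter
        return None

    # pilot adaptation
    lo_t, hi_t = mcmc.target_accept
    for _ in range(mcmc.pilot_runs):
        acc_local, acc_M = sweep(mcmc.pilot_len, adapt_count=True)
        rate_p = acc_local["p"] / mcmc.pilot_len
        s_p *= np.where(rate_p > hi_t, 1.3, np.where(rate_p < lo_t, 1 / 1.3, 1.0))
        rate_s = acc_local["sigma"] / mcmc.pilot_len
        s_sig *= np.where(rate_s > hi_t, 1.3, np.where(rate_s < lo_t, 1 / 1.3, 1.0))
        rate_pi = acc_local["pi"] / mcmc.pilot_len
        s_pi *= np.where(rate_pi > hi_t, 1.3, np.where(rate_pi < lo_t, 1 / 1.3, 1.0))
        rate_M = acc_M / mcmc.pilot_len
        if rate_M > hi_t:
            s_M *= 1.3
        elif rate_M < lo_t:
            s_M /= 1.3
        s_p = np.clip(s_p, 1e-3, 20.0)
        s_sig = np.clip(s_sig, 1e-3, 200.0)
        s_pi = np.clip(s_pi, 1e-3, 20.0)
        s_M = float(np.clip(s_M, 1e-3, 5.0))

    # burn-in
    sweep(mcmc.burn_in)

    # sampling
    samples = np.empty((mcmc.n_samples, D, L))
    delta_draws = np.empty((mcmc.n_samples, L))
    m_draws = np.empty(mcmc.n_samples)
    for t in range(mcmc.n_samples):
        sweep(mcmc.thin)
        samples[t] = sigma
        delta_draws[t] = delta
        m_draws[t] = M

    rows = []
    ess_warnings = []
    for i, dm in enumerate(demes):
        for j, lc in enumerate(locus_ids):
            draws = samples[:, i, j]
            ess = effective_sample_size(draws)
            if ess < 50:
                ess_warnings.append(f"{dm}:{lc} (ESS={ess:.0f})")
            lo_ci, hi_ci = np.quantile(draws, [0.025, 0.975])
            rows.append(
                {
                    "deme": dm,
                    "locus_id": lc,
                    "post_mean": float(draws.mean()),
                    "post_median": float(np.median(draws)),
                    "ci_low": float(lo_ci),
                    "ci_high": float(hi_ci),
                    "ess": ess,
                }
            )
    summary = pd.DataFrame(rows)
    diag = {
        "accept_rate": {k: (acc[k] / max(tries[k], 1)) if k != "M"
                        else acc["M"] / max(tries["M"], 1)
                        for k in acc},
        "ess_warnings": ess_warnings,
        "M_final": M,
        "pi_final": pi.tolist(),
        "delta_final": delta.tolist(),
    }
    return SelectionFit(
        summary=summary,
        sigma_samples=samples,
        demes=list(demes),
        locus_ids=list(locus_ids),
        diagnostics=diag,
        settings=mcmc,
        delta_samples=delta_draws,
        M_samples=m_draws,
    )


def allele_counts_by_population(
    panel: GenotypePanel,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Derived counts and totals (chromosomes with calls) per population x locus."""
    codes = [
        c for c in panel.populations.codes
        if (panel.samples["population_code"] == c).any()
    ]
    derived = np.zeros((len(codes), panel.n_loci))
    totals = np.zeros((len(codes), panel.n_loci))
    for i, code in enumerate(codes):
        mask = (panel.samples["population_code"] == code).to_numpy()
        d = panel.dosages[mask]
        present = d != MISSING
        derived[i] = np.where(present, d, 0).sum(axis=0)
        totals[i] = 2.0 * present.sum(axis=0)
    return derived, totals, codes


def region_summary(
    fit: SelectionFit, regions: dict[str, list[str]]
) -> pd.DataFrame:
    """Mean posterior-mean sigma over the loci of each named region, per deme.

    ``regions`` maps region name -> list of member locus ids; regions must be
    non-empty and reference loci present in the fit.
    """
    means = fit.sigma_mean()
    rows = []
    for name, loci in regions.items():
        if not loci:
            raise ValueError(f"region {name!r} is empty")
        missing = [l for l in loci if l not in means.columns]
        if missing:
            raise ValueError(f"region {name!r}: unknown loci {missing}")
        sub = means[loci].mean(axis=1)
        for dm in fit.demes:
            rows.append({"region": name, "deme": dm,
                         "mean_sigma": float(sub[dm])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genotype-altitude association


def _code_genotypes(dosages: np.ndarray, mode: str) -> np.ndarray:
    x = dosages.astype(float)
    x[dosages == MISSING] = np.nan
    if mode == "additive":
        return x
    if mode == "dominant":
        return np.where(np.isnan(x), np.nan, (x >= 1).astype(float))
    if mode == "recessive":
        return np.where(np.isnan(x), np.nan, (x == 2).astype(float))
    raise ValueError(f"unknown association mode {mode!r}")


def altitude_association(
    panel: GenotypePanel,
    mode: str = "additive",
    altitudes: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-locus OLS regression of residence altitude on coded genotype.

    Returns columns ``locus_id``, ``beta``, ``se``, ``p``, ``n``.
    Monomorphic (or constant-coded) loci yield NaN rows; a perfect fit
    reports the p-value floor (1e-300) rather than zero.
    """
    if altitudes is None:
        altitudes = np.array(
            [panel.populations.altitude(c)
             for c in panel.samples["population_code"]]
        )
    altitudes = np.asarray(altitudes, dtype=float)
    if len(np.unique(altitudes)) < 3:
        raise ValueError("association requires >= 3 distinct altitude values")
    coded = _code_genotypes(panel.dosages, mode)
    rows = []
    for j, lid in enumerate(panel.locus_ids):
        x = coded[:, j]
        ok = ~np.isnan(x)
        xs, ys = x[ok], altitudes[ok]
        if len(xs) < 3 or np.ptp(xs) == 0 or np.ptp(ys) == 0:
            rows.append({"locus_id": lid, "beta": np.nan, "se": np.nan,
                         "p": np.nan, "n": int(len(xs))})
            continue
        res = stats.linregress(xs, ys)
        if res.stderr == 0:  # perfect fit: |t| diverges
            p = P_VALUE_FLOOR
        else:
            p = max(float(res.pvalue), P_VALUE_FLOOR)
        rows.append({"locus_id": lid, "beta": float(res.slope),
                     "se": float(res.stderr), "p": p, "n": int(len(xs))})
    return pd.DataFrame(rows)


def altitude_association_by_population(
    panel: GenotypePanel, mode: str = "additive"
) -> pd.DataFrame:
    """Population-level variant: weighted regression of altitude on the
    population mean coded genotype, weights = calls per population."""
    coded = _code_genotypes(panel.dosages, mode)
    codes = [
        c for c in panel.populations.codes
        if (panel.samples["population_code"] == c).any()
    ]
    alt = np.array([panel.populations.altitude(c) for c in codes])
    rows = []
    for j, lid in enumerate(panel.locus_ids):
        xbar, wts = [], []
        for code in codes:
            mask = (panel.samples["population_code"] == code).to_numpy()
            vals = coded[mask, j]
            vals = vals[~np.isnan(vals)]
            if len(vals) == 0:
                xbar.append(np.nan)
                wts.append(0.0)
            else:
                xbar.append(vals.mean())
                wts.append(float(len(vals)))
        xbar = np.asarray(xbar)
        wts = np.asarray(wts)
        ok = ~np.isnan(xbar) & (wts > 0)
        x, y, w = xbar[ok], alt[ok], wts[ok]
        if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append({"locus_id": lid, "beta": np.nan, "se": np.nan,
                         "p": np.nan, "n": int(len(x))})
            continue
        wsum = w.sum()
        xm = np.sum(w * x) / wsum
        ym = np.sum(w * y) / wsum
        sxx = np.sum(w * (x - xm) ** 2)
        beta = np.sum(w * (x - xm) * (y - ym)) / sxx
        resid = y - ym - beta * (x - xm)
        dof = len(x) - 2
        s2 = np.sum(w * resid**2) / dof
        se = np.sqrt(s2 / sxx)
        if se == 0:
            pval = P_VALUE_FLOOR
        else:
            t = beta / se
            pval = max(2.0 * stats.t.sf(abs(t), dof), P_VALUE_FLOOR)
        rows.append({"locus_id": lid, "beta": float(beta), "se": float(se),
                     "p": float(pval), "n": int(len(x))})
    return pd.DataFrame(rows)
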