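"""REML machinery for crossed random-intercept models.

The screen's replicate structure is summarized with linear mixed models of
the form

    y_i = mu + sum_k u_{k, level_k(i)} + eps_i,   u_k ~ N(0, sigma_k^2 I),
    eps_i ~ N(0, sigma_e^2)

with every grouping factor (individual, plate, run, sex, generation,
concentration, ...) entering as an independent random intercept. Two uses:

* variance-component analysis (VCA): per-feature proportions of variance
  attributable to each factor, proportions = component / total;
* replicate summarization: per-DRP fits with random intercepts for
  individual and plate; the individual BLUPs are the batch-adjusted
  phenotypes carried forward to mapping.

Estimation is EM-REML on Henderson's mixed-model equations (MME): each
iteration solves the MME at the current components and updates

    sigma_k^2 <- (u_k' u_k + sigma_e^2 tr(C^kk)) / q_k
    sigma_e^2 <- (y'y - s' W'y) / (n - p)

where C^kk is the k-th diagonal block of the inverse MME coefficient matrix.
These updates increase the REML likelihood monotonically and keep all
components nonnegative. The coefficient matrix is small (one row per factor
level), so crossed unbalanced designs pose no difficulty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse


@dataclass(frozen=True)
class MixedModelSpec:
    """Response column and random-intercept grouping factors."""

    response: str
    factors: tuple


@dataclass
class VarianceDecomposition:
    """Per-factor variance components and their proportions of the total."""

    components: dict  # factor -> variance (>= 0); includes "residual"
    dropped: tuple = ()

    @property
    def total(self) -> float:
        return float(sum(self.components.values()))

    @property
    def proportions(self) -> dict:
        tot = self.total
        return {k: v / tot for k, v in self.components.items()}


@dataclass
class RemlResult:
    """REML estimates, BLUPs per factor level, and fit diagnostics."""

    variance: VarianceDecomposition
    blups: dict  # factor -> pd.Series indexed by level
    intercept: float
    converged: bool
    n_iter: int
    loglik: float
    flags: tuple = ()


def _factor_matrix(labels) -> tuple:
    codes, levels = pd.factorize(labels, sort=True)
    n = len(codes)
    Z = sparse.coo_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, len(levels))
    ).tocsr()
    return Z, list(levels)


def _reml_loglik(n, p, q_sizes, sig, sig_e, logdet_C, ypy) -> float:
    """-2 log REML likelihood up to a constant, negated to a loglik."""
    val = n * np.log(sig_e) + float(
        sum(q * np.log(s) for q, s in zip(q_sizes, sig))
    ) + logdet_C + ypy
    return -0.5 * val


def reml_fit(
    data: pd.DataFrame,
    response: str,
    factors,
    tol: float = 1e-8,
    max_iter: int = 500,
    polish: bool = True,
) -> RemlResult:
    """Fit a crossed random-intercept model by EM-REML.

    EM iterations are monotone in the REML likelihood but slow down badly
    near a zero component, so by default the EM estimates seed a direct
    Nelder-Mead maximization of the REML likelihood over log variances
    (``polish``); components driven below a relative floor are reported as
    exactly 0. Factors with a single level are dropped with a warning; a
    factor with one observation per level (confounded with the residual)
    gets a zero component and a flag. Missing responses are rejected.
    """
    y = data[response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite responses")
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 observations")

    kept, dropped, flags = [], [], []
    Zs, level_lists = [], []
    for f in factors:
        Z, levels = _factor_matrix(data[f])
        if len(levels) < 2:
            warnings.warn(f"factor {f!r} has a single level; dropped")
            dropped.append(f)
            continue
        kept.append(f)
        Zs.append(Z)
        level_lists.append(levels)

    if not kept:
        mu = float(y.mean())
        resid = float(np.var(y - mu, ddof=1)) if n > 1 else 0.0
        vd = VarianceDecomposition({"residual": resid}, tuple(dropped))
        return RemlResult(vd, {}, mu, True, 0, np.nan, tuple(flags))

    # a factor with one observation per level and nothing else to separate it
    # from the residual is non-identifiable
    identifiable = np.ones(len(kept), dtype=bool)
    for j, f in enumerate(kept):
        if Zs[j].shape[1] == n:
            identifiable[j] = False
            flags.append(f"factor {f!r} non-identifiable (one observation per level)")
            warnings.warn(flags[-1])

    X = np.ones((n, 1))
    W = sparse.hstack([sparse.csr_matrix(X)] + Zs, format="csr")
    WtW = (W.T @ W).toarray()
    Wty = W.T @ y
    yty = float(y @ y)
    p = 1
    q_sizes = [Z.shape[1] for Z in Zs]
    offsets = np.cumsum([p] + q_sizes)

    var_y = float(np.var(y, ddof=1))
    if var_y == 0.0:
        comps = {f: 0.0 for f in kept}
        comps["residual"] = 0.0
        vd = VarianceDecomposition(comps, tuple(dropped))
        blups = {
            f: pd.Series(np.zeros(len(lv)), index=lv) for f, lv in zip(kept, level_lists)
        }
        return RemlResult(vd, blups, float(y.mean()), True, 0, np.nan, tuple(flags))

    k = len(kept)
    sig = np.full(k, var_y / (k + 1))
    sig[~identifiable] = 0.0
    sig_e = var_y / (k + 1)
    floor = 1e-12 * var_y

    converged = False
    loglik = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        C = WtW.copy()
        for j in range(k):
            lo, hi = offsets[j], offsets[j + 1]
            ratio = sig_e / sig[j] if sig[j] > floor else 1.0 / floor
            C[lo:hi, lo:hi] += np.eye(q_sizes[j]) * ratio
        try:
            Cinv = np.linalg.inv(C)
        except np.linalg.LinAlgError:
            Cinv = np.linalg.pinv(C)
        s = Cinv @ Wty
        new_sig = sig.copy()
        for j in range(k):
            if not identifiable[j]:
                continue
            lo, hi = offsets[j], offsets[j + 1]
            u = s[lo:hi]
            tr = np.trace(Cinv[lo:hi, lo:hi])
            new_sig[j] = (float(u @ u) + sig_e * tr) / q_sizes[j]
        new_sig_e = (yty - float(s @ Wty)) / (n - p)
        new_sig = np.maximum(new_sig, 0.0)
        new_sig_e = max(new_sig_e, floor)
        delta = max(
            np.max(np.abs(new_sig - sig)), abs(new_sig_e - sig_e)
        ) / max(var_y, floor)
        sig, sig_e = new_sig, new_sig_e
        if delta < tol:
            converged = True
            break

    if polish:
        from scipy.optimize import minimize

        free = np.flatnonzero(identifiable)
        # clip so the objective flattens at negligible variance instead of
        # chasing the boundary to -inf
        lo_log = np.log(1e-10 * var_y)
        hi_log = np.log(1e6 * var_y)

        def neg2(theta):
            theta = np.clip(theta, lo_log, hi_log)
            s_all = sig.copy()
            s_all[free] = np.exp(theta[:-1])
            s_e = np.exp(theta[-1])
            C = WtW.copy()
            for j in range(k):
                lo, hi = offsets[j], offsets[j + 1]
                ratio = s_e / s_all[j] if s_all[j] > floor else 1.0 / floor
                C[lo:hi, lo:hi] += np.eye(q_sizes[j]) * ratio
            sign, logdet_scaled = np.linalg.slogdet(C / s_e)
            if sign <= 0:
                return np.inf
            sol = np.linalg.solve(C, Wty)
            ypy = (yty - float(sol @ Wty)) / s_e
            det_term = float(sum(q_sizes[j] * np.log(s_all[j]) for j in free))
            return n * np.log(s_e) + det_term + logdet_scaled + ypy

        if free.size:
            theta0 = np.log(
                np.concatenate([np.maximum(sig[free], 1e-8 * var_y), [sig_e]])
            )
            opt = minimize(
                neg2, theta0, method="Nelder-Mead",
                options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 1500},
            )
            if np.isfinite(opt.fun) and opt.fun <= neg2(theta0) + 1e-12:
                x = np.clip(opt.x, lo_log, hi_log)
                sig[free] = np.exp(x[:-1])
                sig_e = float(np.exp(x[-1]))
            converged = True
        sig[sig < 1e-6 * var_y] = 0.0

    # final solve + loglik at the estimates
    C = WtW.copy()
    for j in range(k):
        lo, hi = offsets[j], offsets[j + 1]
        ratio = sig_e / sig[j] if sig[j] > floor else 1.0 / floor
        C[lo:hi, lo:hi] += np.eye(q_sizes[j]) * ratio
    sign, logdet_scaled = np.linalg.slogdet(C / sig_e)
    Cinv = np.linalg.inv(C) if sign > 0 else np.linalg.pinv(C)
    s = Cinv @ Wty
    ypy = (yty - float(s @ Wty)) / sig_e
    sig_for_det = np.where(sig > floor, sig, floor)
    loglik = _reml_loglik(n, p, q_sizes, sig_for_det, sig_e, logdet_scaled, ypy)

    comps = {f: float(max(sj, 0.0) if sj > floor else 0.0) for f, sj in zip(kept, sig)}
    comps["residual"] = float(sig_e)
    vd = VarianceDecomposition(comps, tuple(dropped))
    blups = {}
    for j, f in enumerate(kept):
        lo, hi = offsets[j], offsets[j + 1]
        vals = s[lo:hi] if comps[f] > 0 else np.zeros(q_sizes[j])
        blups[f] = pd.Series(vals, index=level_lists[j])
    return RemlResult(vd, blups, float(s[0]), converged, it, loglik, tuple(flags))


#: Eq-1 style VCA factor set; concentration enters as a categorical factor.
DEFAULT_VCA_FACTORS = ("sex", "run", "generation", "individual_id", "plate", "concentration")


def decompose_feature_variance(
    well_table: pd.DataFrame,
    factors=DEFAULT_VCA_FACTORS,
) -> pd.DataFrame:
    """Variance-component analysis per feature on well-level values.

    Returns a tidy frame (feature, factor, variance, proportion). The dose
    column is treated as the categorical 'concentration' factor.
    """
    df = well_table.copy()
    if "concentration" in factors and "concentration" not in df.columns:
        df["concentration"] = df["dose_um"].astype(str)
    out = []
    for feat, sub in df.groupby("feature", sort=False):
        present = [f for f in factors if f in sub.columns]
        res = reml_fit(sub, "value", present)
        props = res.variance.proportions
        for fac, var in res.variance.components.items():
            out.append((feat, fac, var, props[fac]))
    return pd.DataFrame(out, columns=["feature", "factor", "variance", "proportion"])


def blup_adjust(drp_table: pd.DataFrame, drps=None) -> pd.DataFrame:
    """Batch-adjust replicate-level DRPs and summarize per individual.

    Per (feature, drp) fits ``value ~ 1 + (1|individual) + (1|plate)`` on the
    converged replicates and returns the individual BLUPs: the plate effect
    is absorbed by its own random intercept and discarded. Individuals with
    no converged replicate for a DRP are absent from that DRP's output.

    Returns a tidy frame (individual_id, feature, drp, value); ``drps``
    optionally restricts to a subset of DRP names.
    """
    usable = drp_table[drp_table["converged"] & np.isfinite(drp_table["value"])]
    if drps is not None:
        usable = usable[usable["drp"].isin(drps)]
    rows = []
    for (feat, drp), sub in usable.groupby(["feature", "drp"], sort=False):
        res = reml_fit(sub, "value", ("individual_id", "plate"), max_iter=100)
        blups = res.blups.get("individual_id")
        if blups is None:  # single individual: nothing to separate
            continue
        for ind, val in blups.items():
            rows.append((ind, feat, drp, float(val)))
    return pd.DataFrame(rows, columns=["individual_id", "feature", "drp", "value"])
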