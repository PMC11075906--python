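"""Four-parameter log-logistic (LL.4) dose-response fitting and trait extraction.

The LL.4 curve is

    f(x) = c + (d - c) / (1 + exp(b * (log x - log e)))

with slope ``b``, lower asymptote ``c``, upper asymptote ``d`` and
inflection dose ``e`` (the EC50). At the zero-dose control the curve is
evaluated as its analytic limit (``d`` for b > 0, ``c`` for b < 0) so that
control wells anchor the baseline asymptote instead of being dropped.

From each converged fit nine dose-response parameters are extracted as
per-individual quantitative traits: the starting (zero-dose) asymptote, the
maximum (opposite-limit) asymptote, the slope, and the effective
concentrations EC5, EC10, EC25, EC50, EC75 and EC90. ECp is the dose at
which the response has moved p% of the asymptote span away from the
zero-dose baseline; in closed form ECp = e * (p / (100 - p))^(1/|b|).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

#: The nine dose-response parameter (DRP) names extracted per fit.
DRP_NAMES = (
    "start_asymptote",
    "max_asymptote",
    "slope",
    "EC05",
    "EC10",
    "EC25",
    "EC50",
    "EC75",
    "EC90",
)

_EC_PERCENTS = {"EC05": 5.0, "EC10": 10.0, "EC25": 25.0, "EC50": 50.0, "EC75": 75.0, "EC90": 90.0}

# Exponent clip keeping exp() finite while preserving the saturated limits.
_EXP_CLIP = 500.0


def _safe_log_doses(x: np.ndarray) -> np.ndarray:
    """log doses with x = 0 mapped far below the smallest positive dose, so
    the curve evaluates to its analytic zero-dose limit."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x > 0
    out[pos] = np.log(x[pos])
    if (~pos).any():
        floor = (np.log(x[pos].min()) if pos.any() else 0.0) - 700.0
        out[~pos] = floor
    return out


def ll4(x, b: float, c: float, d: float, e: float) -> np.ndarray:
    """Evaluate the LL.4 curve; dose 0 yields the analytic limit."""
    if e <= 0:
        raise ValueError("inflection dose e must be positive")
    lx = _safe_log_doses(np.asarray(x, dtype=float))
    t = np.clip(b * (lx - np.log(e)), -_EXP_CLIP, _EXP_CLIP)
    return c + (d - c) / (1.0 + np.exp(t))


@dataclass(frozen=True)
class LL4Fit:
    """A fitted LL.4 curve."""

    b: float
    c: float
    d: float
    e: float
    converged: bool
    residual_sd: float
    log_scale: bool
    n_points: int = 0

    def predict(self, x) -> np.ndarray:
        return ll4(x, self.b, self.c, self.d, self.e)


@dataclass(frozen=True)
class DrpSet:
    """The nine dose-response traits from one fit, with provenance."""

    individual: str
    feature: str
    replicate: object
    start_asymptote: float
    max_asymptote: float
    slope: float
    EC05: float
    EC10: float
    EC25: float
    EC50: float
    EC75: float
    EC90: float

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in DRP_NAMES}


def _residuals_and_jac(theta, lx, y):
    b, c, d, log_e = theta
    t = np.clip(b * (lx - log_e), -_EXP_CLIP, _EXP_CLIP)
    et = np.exp(t)
    inv = 1.0 / (1.0 + et)
    f = c + (d - c) * inv
    # d f / d theta
    dinv = -et * inv * inv
    jac = np.empty((lx.size, 4))
    jac[:, 0] = (d - c) * dinv * (lx - log_e)
    jac[:, 1] = 1.0 - inv
    jac[:, 2] = inv
    jac[:, 3] = (d - c) * dinv * (-b)
    return f - y, jac


def _self_start(lx, y, pos_mask):
    """Starting values: asymptotes from per-dose extremes, e from the
    geometric mean of positive doses, b from a logit linearization."""
    order = np.argsort(lx)
    y_lo, y_hi = float(np.min(y)), float(np.max(y))
    span = y_hi - y_lo
    # direction: decreasing response with dose => baseline is upper => b > 0
    slope_sign = 1.0 if np.corrcoef(lx[order], y[order])[0, 1] <= 0 else -1.0
    d0 = y_hi if slope_sign > 0 else y_lo
    c0 = y_lo if slope_sign > 0 else y_hi
    log_e0 = float(np.mean(lx[pos_mask])) if pos_mask.any() else 0.0
    # logit linearization on interior points
    frac = np.clip((d0 - y) / (span if span > 0 else 1.0), 0.02, 0.98)
    z = np.log(frac / (1.0 - frac))
    use = pos_mask
    b0 = 1.0 * slope_sign
    if use.sum() >= 2 and np.ptp(lx[use]) > 0:
        coef = np.polyfit(lx[use], z[use], 1)
        if np.isfinite(coef[0]) and abs(coef[0]) > 1e-6:
            b0 = float(coef[0])
            log_e0 = float(-coef[1] / coef[0]) if abs(coef[0]) > 1e-6 else log_e0
    if not np.isfinite(log_e0):
        log_e0 = 0.0
    # keep the start inside a sane window around the dose range
    lo, hi = lx[pos_mask].min() - 3.0, lx[pos_mask].max() + 3.0
    log_e0 = float(np.clip(log_e0, lo, hi))
    b0 = float(np.clip(b0, -50.0, 50.0))
    if b0 == 0.0:
        b0 = slope_sign
    return np.array([b0, c0, d0, log_e0])


def fit_ll4(
    doses,
    responses,
    log_transform: bool = False,
    n_restarts: int = 5,
    seed: int = 0,
) -> LL4Fit:
    """Least-squares fit of the LL.4 model.

    Repeated doses (pooled replicates) are allowed. Fewer than 4 usable
    points or constant responses yield a non-converged fit rather than an
    exception. With ``log_transform`` responses are natural-log transformed
    before fitting (responses must then be positive) and the asymptotes are
    reported on the log scale.
    """
    x = np.asarray(doses, dtype=float).ravel()
    y = np.asarray(responses, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("doses and responses must have equal length")
    ok = np.isfinite(y) & np.isfinite(x)
    x, y = x[ok], y[ok]
    if log_transform:
        if (y <= 0).any():
            raise ValueError("log_transform requires strictly positive responses")
        y = np.log(y)
    failed = LL4Fit(np.nan, np.nan, np.nan, np.nan, False, np.nan, log_transform, int(x.size))
    if x.size < 4 or np.unique(x).size < 4:
        return failed
    if np.ptp(y) == 0.0:
        return failed

    lx = _safe_log_doses(x)
    pos = x > 0
    theta0 = _self_start(lx, y, pos)
    rng = np.random.default_rng(seed)

    def attempt(start):
        try:
            res = least_squares(
                lambda th: _residuals_and_jac(th, lx, y)[0],
                start,
                jac=lambda th: _residuals_and_jac(th, lx, y)[1],
                method="lm",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=400,
            )
        except Exception:
            return None
        if res.status <= 0 or not np.all(np.isfinite(res.x)):
            return None
        return float(2.0 * res.cost), res

    best = attempt(theta0)
    if best is None:
        # jittered restarts before declaring failure
        for _ in range(max(0, n_restarts)):
            jitter = theta0.copy()
            jitter[0] *= np.exp(rng.normal(scale=0.5))
            jitter[3] += rng.normal(scale=1.0)
            span = theta0[2] - theta0[1]
            jitter[1] += rng.normal(scale=0.1 * abs(span) + 1e-6)
            jitter[2] += rng.normal(scale=0.1 * abs(span) + 1e-6)
            cand = attempt(jitter)
            if cand is not None and (best is None or cand[0] < best[0]):
                best = cand

    if best is None:
        return failed
    sse, res = best
    b, c, d, log_e = res.x
    if b == 0.0 or not np.isfinite(log_e):
        return failed
    dof = max(x.size - 4, 1)
    residual_sd = float(np.sqrt(sse / dof))
    return LL4Fit(
        float(b), float(c), float(d), float(np.exp(log_e)), True, residual_sd,
        log_transform, int(x.size),
    )


def effective_concentration(fit: LL4Fit, p: float) -> float:
    """ECp in closed form: the dose where the response has moved p% of the
    asymptote span |d - c| away from the zero-dose baseline.

    ECp = e * (p / (100 - p))^(1 / |b|); for b < 0 (increasing curve) the
    baseline is c and the same expression follows from the mirrored form.
    """
    if not (0.0 < p < 100.0):
        raise ValueError("p must be in (0, 100)")
    if not fit.converged:
        raise ValueError("fit did not converge")
    if fit.b == 0.0:
        raise ValueError("ECp undefined for zero slope")
    return float(fit.e * (p / (100.0 - p)) ** (1.0 / abs(fit.b)))


def extract_drps(fit: LL4Fit, individual: str = "", feature: str = "", replicate=None):
    """Extract the nine dose-response traits; ``None`` for a non-converged fit
    (the replicate is treated as absent downstream)."""
    if not fit.converged:
        return None
    start = fit.d if fit.b > 0 else fit.c
    maximum = fit.c if fit.b > 0 else fit.d
    ecs = {name: effective_concentration(fit, pct) for name, pct in _EC_PERCENTS.items()}
    return DrpSet(
        individual=individual,
        feature=feature,
        replicate=replicate,
        start_asymptote=float(start),
        max_asymptote=float(maximum),
        slope=float(fit.b),
        **ecs,
    )


def fit_drp_table(
    well_table: pd.DataFrame,
    log_transform: bool = False,
    pool_replicates: bool = False,
    n_restarts: int = 5,
    seed: int = 0,
    max_extrapolation: float = 10.0,
) -> pd.DataFrame:
    """Fit LL.4 per individual x feature x replicate column and return a long
    DRP table.

    Columns: individual_id, feature, replicate, plate, drp, value, converged.
    One fit per technical replicate column by default; ``pool_replicates``
    pools the four columns into a single fit per individual x feature. Each
    DRP row carries the plate of its replicate column so the downstream
    batch adjustment can absorb inter-plate effects.

    Replicate fits whose EC50 extrapolates beyond ``max_extrapolation`` times
    outside the tested dose range carry no information about the inflection
    (the curve never turned within the design) and are flagged as missing;
    set ``max_extrapolation=None`` to keep them.
    """
    group_cols = ["individual_id", "feature"]
    if not pool_replicates:
        group_cols.append("replicate_column")
    pos_doses = well_table.loc[well_table["dose_um"] > 0, "dose_um"]
    ec_lo = pos_doses.min() / max_extrapolation if max_extrapolation else 0.0
    ec_hi = pos_doses.max() * max_extrapolation if max_extrapolation else np.inf
    rows = []
    for key, sub in well_table.groupby(group_cols, sort=False):
        if pool_replicates:
            ind, feat = key
            rep = "pooled"
        else:
            ind, feat, rep = key
        plate = sub["plate"].iloc[0]
        fit = fit_ll4(
            sub["dose_um"].to_numpy(),
            sub["value"].to_numpy(),
            log_transform=log_transform,
            n_restarts=n_restarts,
            seed=seed,
        )
        drps = extract_drps(fit, individual=ind, feature=feat, replicate=rep)
        if drps is not None and not (ec_lo <= drps.EC50 <= ec_hi):
            drps = None
        if drps is None:
            rows.append((ind, feat, rep, plate, "EC50", np.nan, False))
            continue
        for name, value in drps.as_dict().items():
            rows.append((ind, feat, rep, plate, name, value, True))
        # log-EC50 as an additional mapping trait: EC50s are close to
        # lognormal across individuals, so the batch adjustment behaves far
        # better on the log scale
        rows.append((ind, feat, rep, plate, "log_EC50", float(np.log(drps.EC50)), True))
    return pd.DataFrame(
        rows,
        columns=["individual_id", "feature", "replicate", "plate", "drp", "value", "converged"],
    )
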