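"""Bundle-value models: fitting, comparison, stratification, curve evaluation.

Four families describe how the bid for a bundle relates to the bids for its
members vi, vj:

    linear       v_ij = b0 + b1*vi + b2*vj
    power        v_ij = b0 + b1*vi**b2 + b3*vj**b4
    logarithmic  v_ij = b0 + b1*log(b3 + vi) + b4*log(b5 + vj)
    divnorm      v_ij = b0 + b1*(vi + vj) / (sigma + vi + vj)

Sub-additivity appears as linear slopes below one, or as concavity of the
nonlinear families. Each family can be fitted three ways: pooled fixed
effects; per-subject fixed effects whose BIC is summed across participants
(the headline comparison metric); or a mixed-effects model with subject
random effects on the intercept and the leading scale coefficient — exact
marginal likelihood for the linear family (statsmodels MixedLM) and a
Laplace-approximate nonlinear mixed model for the rest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

import statsmodels.formula.api as smf

from .synth import FAMILIES

_SIGMA_FLOOR = 1e-6
_EXP_HI = 5.0  # box constraint on power exponents

LOG2PI = np.log(2.0 * np.pi)


class FitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# family definitions: prediction, analytic jacobian, warm starts, bounds

def _linear_predict(p, vi, vj):
    return p[0] + p[1] * vi + p[2] * vj


def _linear_jac(p, vi, vj):
    return np.column_stack([np.ones_like(vi), vi, vj])


def _power_predict(p, vi, vj):
    return p[0] + p[1] * vi ** p[2] + p[3] * vj ** p[4]


def _power_jac(p, vi, vj):
    vi_p, vj_p = vi ** p[2], vj ** p[4]
    # v**b * log(v) -> 0 as v -> 0 for b > 0
    dlog_i = np.where(vi > 0, vi_p * np.log(np.maximum(vi, 1e-300)), 0.0)
    dlog_j = np.where(vj > 0, vj_p * np.log(np.maximum(vj, 1e-300)), 0.0)
    return np.column_stack(
        [np.ones_like(vi), vi_p, p[1] * dlog_i, vj_p, p[3] * dlog_j]
    )


def _log_predict(p, vi, vj):
    return p[0] + p[1] * np.log(p[2] + vi) + p[3] * np.log(p[4] + vj)


def _log_jac(p, vi, vj):
    li, lj = np.log(p[2] + vi), np.log(p[4] + vj)
    return np.column_stack(
        [np.ones_like(vi), li, p[1] / (p[2] + vi), lj, p[3] / (p[4] + vj)]
    )


def _divnorm_predict(p, vi, vj):
    w = vi + vj
    return p[0] + p[1] * w / (p[2] + w)


def _divnorm_jac(p, vi, vj):
    w = vi + vj
    den = p[2] + w
    return np.column_stack(
        [np.ones_like(vi), w / den, -p[1] * w / den**2]
    )


@dataclass(frozen=True)
class _Family:
    name: str
    param_names: tuple[str, ...]
    predict: callable
    jac: callable
    lower: tuple[float, ...]
    upper: tuple[float, ...]


_INF = np.inf
_FAMILY_TABLE: dict[str, _Family] = {
    "linear": _Family(
        "linear", ("beta0", "beta1", "beta2"), _linear_predict, _linear_jac,
        (-_INF, -_INF, -_INF), (_INF, _INF, _INF),
    ),
    "power": _Family(
        "power", ("beta0", "beta1", "beta2", "beta3", "beta4"),
        _power_predict, _power_jac,
        (-_INF, -_INF, 1e-3, -_INF, 1e-3), (_INF, _INF, _EXP_HI, _INF, _EXP_HI),
    ),
    "logarithmic": _Family(
        "logarithmic", ("beta0", "beta1", "beta3", "beta4", "beta5"),
        _log_predict, _log_jac,
        (-_INF, -_INF, 1e-3, -_INF, 1e-3), (_INF, _INF, _INF, _INF, _INF),
    ),
    "divnorm": _Family(
        "divnorm", ("beta0", "beta1", "sigma"), _divnorm_predict, _divnorm_jac,
        (-_INF, -_INF, _SIGMA_FLOOR), (_INF, _INF, _INF),
    ),
}


def _warm_start(family: _Family, vi, vj, y) -> np.ndarray:
    """Linear least-squares warm start mapped into each family's space."""
    X = np.column_stack([np.ones_like(vi), vi, vj])
    b, *_ = np.linalg.lstsq(X, y, rcond=None)
    if family.name == "linear":
        return b
    if family.name == "power":
        return np.array([b[0], b[1], 1.0, b[2], 1.0])
    if family.name == "logarithmic":
        Xl = np.column_stack([np.ones_like(vi), np.log1p(vi), np.log1p(vj)])
        bl, *_ = np.linalg.lstsq(Xl, y, rcond=None)
        return np.array([bl[0], bl[1], 1.0, bl[2], 1.0])
    # divnorm: pick sigma at the median context sum, regress on the basis
    w = vi + vj
    sigma0 = max(float(np.median(w)), 1.0)
    Xd = np.column_stack([np.ones_like(w), w / (sigma0 + w)])
    bd, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    return np.array([bd[0], bd[1], sigma0])


@dataclass
class BundleModelSpec:
    """Which family to fit and with what random-effects structure."""

    family: str = "linear"
    random_effects: bool = True
    n_starts: int = 5
    start_seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class BundleModelFit:
    family: str
    method: str  # "fixed" | "per_subject" | "mixed"
    params: dict[str, float]
    se: dict[str, float] | None
    random_effects: pd.DataFrame | None
    loglik: float
    bic: float
    r2: float
    n_obs: int
    n_params: int
    converged: bool
    message: str = ""
    per_subject_params: pd.DataFrame | None = None
    variance_components: dict[str, float] = field(default_factory=dict)

    def predict(self, vi, vj) -> np.ndarray:
        fam = _FAMILY_TABLE[self.family]
        p = np.array([self.params[n] for n in fam.param_names])
        return np.asarray(fam.predict(p, np.asarray(vi, float), np.asarray(vj, float)))


def _bundle_arrays(wtp: pd.DataFrame):
    """Extract (vi, vj, y, subject) for bundle records, vi/vj = member item bids.

    The member value used as the regressor is the subject's same-day bid on
    that item (the behavioral measure of its value).
    """
    bundles = wtp[wtp.trial_type == "bundle"]
    if bundles.empty:
        raise FitError("no bundle records")
    items = wtp[wtp.trial_type == "item"]
    key = {
        (r.subject_id, r.day, int(r.item_id)): r.bid
        for r in items.itertuples(index=False)
    }
    vi = np.array(
        [key[(r.subject_id, r.day, int(r.left_item))] for r in bundles.itertuples(index=False)]
    )
    vj = np.array(
        [key[(r.subject_id, r.day, int(r.right_item))] for r in bundles.itertuples(index=False)]
    )
    return vi, vj, bundles.bid.to_numpy(float), bundles.subject_id.to_numpy()


def _gaussian_ml_stats(rss: float, n: int, k_mean: int):
    """Profile-ML Gaussian log-likelihood, BIC (k counts the variance too)."""
    s2 = max(rss / n, 1e-300)
    ll = -0.5 * n * (LOG2PI + np.log(s2) + 1.0)
    k = k_mean + 1
    return ll, -2.0 * ll + k * np.log(n), k


def _nls_fit(family: _Family, vi, vj, y, n_starts=5, seed=0):
    """Multi-start bounded nonlinear least squares with analytic jacobian."""
    rng = np.random.default_rng(seed)
    p0 = _warm_start(family, vi, vj, y)
    lo = np.array(family.lower)
    hi = np.array(family.upper)
    starts = [np.clip(p0, lo + 1e-9, hi - 1e-9)]
    for _ in range(max(n_starts - 1, 0)):
        jitter = p0 * (1 + 0.3 * rng.standard_normal(p0.size)) + 0.1 * rng.standard_normal(p0.size)
        starts.append(np.clip(jitter, lo + 1e-9, hi - 1e-9))
    best = None
    for s in starts:
        res = optimize.least_squares(
            lambda p: family.predict(p, vi, vj) - y,
            s,
            jac=lambda p: family.jac(p, vi, vj),
            bounds=(lo, hi),
            method="trf",
            max_nfev=400,
        )
        if best is None or res.cost < best.cost:
            best = res
    return best


def fit_fixed_effects(wtp: pd.DataFrame, spec: BundleModelSpec) -> BundleModelFit:
    """Pooled fixed-effects fit (all subjects share one parameter vector)."""
    fam = _FAMILY_TABLE[spec.family]
    vi, vj, y, _ = _bundle_arrays(wtp)
    res = _nls_fit(fam, vi, vj, y, spec.n_starts, spec.start_seed)
    rss = float(2 * res.cost)
    n = y.size
    ll, bic, k = _gaussian_ml_stats(rss, n, len(fam.param_names))
    tss = float(((y - y.mean()) ** 2).sum())
    se = _nls_se(res, rss, n)
    return BundleModelFit(
        family=spec.family, method="fixed",
        params=dict(zip(fam.param_names, res.x)),
        se=dict(zip(fam.param_names, se)),
        random_effects=None, loglik=ll, bic=bic,
        r2=1.0 - rss / tss if tss > 0 else np.nan,
        n_obs=n, n_params=k, converged=bool(res.success),
        message=res.message,
    )


def _nls_se(res, rss, n):
    dof = max(n - res.x.size, 1)
    s2 = rss / dof
    try:
        cov = s2 * np.linalg.pinv(res.jac.T @ res.jac)
        return np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        return np.full(res.x.size, np.nan)


def fit_per_subject(wtp: pd.DataFrame, spec: BundleModelSpec) -> BundleModelFit:
    """Independent fixed-effects fit per participant; BIC summed across them.

    This is the aggregation behind the headline model-comparison table:
    every participant gets their own parameters and the reported BIC is the
    sum of the per-participant BICs.
    """
    fam = _FAMILY_TABLE[spec.family]
    vi, vj, y, subj = _bundle_arrays(wtp)
    rows, ll_sum, bic_sum, rss_sum, tss_sum, n_tot = [], 0.0, 0.0, 0.0, 0.0, 0
    ok = True
    for s in np.unique(subj):
        m = subj == s
        res = _nls_fit(fam, vi[m], vj[m], y[m], spec.n_starts, spec.start_seed)
        ok &= bool(res.success)
        rss = float(2 * res.cost)
        ll, bic, _ = _gaussian_ml_stats(rss, int(m.sum()), len(fam.param_names))
        ll_sum += ll
        bic_sum += bic
        rss_sum += rss
        tss_sum += float(((y[m] - y[m].mean()) ** 2).sum())
        n_tot += int(m.sum())
        rows.append({"subject_id": s, **dict(zip(fam.param_names, res.x))})
    per = pd.DataFrame(rows)
    mean_params = {n: float(per[n].mean()) for n in fam.param_names}
    return BundleModelFit(
        family=spec.family, method="per_subject", params=mean_params, se=None,
        random_effects=None, loglik=ll_sum, bic=bic_sum,
        r2=1.0 - rss_sum / tss_sum if tss_sum > 0 else np.nan,
        n_obs=n_tot, n_params=(len(fam.param_names) + 1) * per.shape[0],
        converged=ok, per_subject_params=per,
    )


# ---------------------------------------------------------------------------
# mixed-effects fits

def _fit_linear_mixed(wtp: pd.DataFrame, reml: bool = False) -> BundleModelFit:
    """Linear mixed model: random intercept and a shared random slope on vi+vj."""
    vi, vj, y, subj = _bundle_arrays(wtp)
    df = pd.DataFrame(
        {"y": y, "vi": vi, "vj": vj, "vsum": vi + vj, "subject": subj}
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("y ~ vi + vj", df, groups=df.subject, re_formula="~vsum")
        res = model.fit(reml=reml, method="lbfgs")
    fe = res.fe_params
    params = {"beta0": fe["Intercept"], "beta1": fe["vi"], "beta2": fe["vj"]}
    se = {"beta0": res.bse["Intercept"], "beta1": res.bse["vi"], "beta2": res.bse["vj"]}
    k = 3 + 3 + 1  # fixed effects + RE covariance (2x2 symmetric) + residual
    n = len(df)
    bic = -2.0 * res.llf + k * np.log(n)
    fitted = res.fittedvalues  # includes BLUP random-effect contributions
    rss = float(((y - fitted) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    re = pd.DataFrame(
        [{"subject_id": g, "u0": v.iloc[0], "u1": v.iloc[1]} for g, v in res.random_effects.items()]
    )
    ci = res.conf_int()
    fit = BundleModelFit(
        family="linear", method="mixed", params={k_: float(v) for k_, v in params.items()},
        se={k_: float(v) for k_, v in se.items()}, random_effects=re,
        loglik=float(res.llf), bic=float(bic), r2=1.0 - rss / tss,
        n_obs=n, n_params=k, converged=bool(res.converged),
        variance_components={
            "re_var_intercept": float(res.cov_re.iloc[0, 0]),
            "re_var_slope": float(res.cov_re.iloc[1, 1]),
            "resid_var": float(res.scale),
        },
    )
    fit.conf_int = {  # type: ignore[attr-defined]
        "beta0": tuple(ci.loc["Intercept"]),
        "beta1": tuple(ci.loc["vi"]),
        "beta2": tuple(ci.loc["vj"]),
    }
    return fit


class _LaplaceNLME:
    """Nonlinear mixed model via joint penalized fit + Laplace marginal.

    Random effects: additive on the intercept (param 0) and the leading
    scale coefficient (param 1), per subject, with diagonal covariance.
    """

    def __init__(self, family: _Family, vi, vj, y, subj):
        self.fam = family
        self.vi, self.vj, self.y = vi, vj, y
        self.subjects = np.unique(subj)
        self.sidx = np.searchsorted(self.subjects, subj)
        self.n = y.size
        self.ns = self.subjects.size
        self.kf = len(family.param_names)

    def _expand(self, theta, b):
        """Per-observation parameter matrix with subject offsets applied."""
        P = np.tile(theta, (self.n, 1))
        P[:, 0] += b[self.sidx, 0]
        P[:, 1] += b[self.sidx, 1]
        return P

    def _predict_rows(self, theta, b):
        P = self._expand(theta, b)
        # family predicts rowwise; all families are vectorized over params
        return self.fam.predict(P.T, self.vi, self.vj)

    def _resid(self, x, sig_e, tau):
        theta = x[: self.kf]
        b = x[self.kf :].reshape(self.ns, 2)
        r = (self._predict_rows(theta, b) - self.y) / sig_e
        pen = (b / tau[None, :]).ravel()
        return np.concatenate([r, pen])

    def _jac(self, x, sig_e, tau):
        theta = x[: self.kf]
        b = x[self.kf :].reshape(self.ns, 2)
        P = self._expand(theta, b)
        Jfam = self.fam.jac(P.T, self.vi, self.vj)  # n x kf
        J = np.zeros((self.n + 2 * self.ns, self.kf + 2 * self.ns))
        J[: self.n, : self.kf] = Jfam / sig_e
        for col in (0, 1):
            J[np.arange(self.n), self.kf + 2 * self.sidx + col] = (
                Jfam[:, col] / sig_e
            )
        idx = np.arange(2 * self.ns)
        J[self.n + idx, self.kf + idx] = 1.0 / tau[idx % 2]
        return J

    def _inner(self, psi, x0):
        sig_e, tau = np.exp(psi[0]), np.exp(psi[1:])
        lo = np.concatenate([self.fam.lower, np.full(2 * self.ns, -np.inf)])
        hi = np.concatenate([self.fam.upper, np.full(2 * self.ns, np.inf)])
        res = optimize.least_squares(
            self._resid, np.clip(x0, lo + 1e-9, hi - 1e-9),
            jac=self._jac, args=(sig_e, tau), bounds=(lo, hi),
            method="trf", max_nfev=200,
        )
        return res

    def loglik(self, psi, res):
        """Laplace-approximate marginal log-likelihood at the joint mode."""
        sig_e, tau = np.exp(psi[0]), np.exp(psi[1:])
        theta = res.x[: self.kf]
        b = res.x[self.kf :].reshape(self.ns, 2)
        r = self._predict_rows(theta, b) - self.y
        P = self._expand(theta, b)
        Jfam = self.fam.jac(P.T, self.vi, self.vj)
        Jb = Jfam[:, :2]  # derivative wrt the two random effects
        ll = -0.5 * self.n * (LOG2PI + 2 * np.log(sig_e))
        ll -= 0.5 * float(r @ r) / sig_e**2
        D = tau**2
        for s in range(self.ns):
            m = self.sidx == s
            Js = Jb[m]
            G = (Js.T @ Js) / sig_e**2  # 2x2
            H = G + np.diag(1.0 / D)
            ll -= 0.5 * float(b[s] @ (b[s] / D))
            sign, logdet = np.linalg.slogdet(np.diag(D) @ H)
            ll -= 0.5 * logdet
        return ll

    def fit(self, n_starts=3, seed=0):
        # warm start: pooled fixed fit for theta, zero random effects
        pooled = _nls_fit(self.fam, self.vi, self.vj, self.y, n_starts, seed)
        theta0 = pooled.x
        rss0 = 2 * pooled.cost
        sig0 = np.sqrt(max(rss0 / self.n, 1e-6))
        psi0 = np.array([np.log(sig0), np.log(max(0.3, 0.1 * sig0)), np.log(0.05)])
        x0 = np.concatenate([theta0, np.zeros(2 * self.ns)])
        state = {"x": x0}

        def neg_ll(psi):
            psi = np.clip(psi, -6.0, 4.0)
            res = self._inner(psi, state["x"])
            state["x"] = res.x
            return -self.loglik(psi, res)

        opt = optimize.minimize(
            neg_ll, psi0, method="Nelder-Mead",
            options={"maxiter": 60, "xatol": 2e-2, "fatol": 1e-2},
        )
        psi = np.clip(opt.x, -6.0, 4.0)
        res = self._inner(psi, state["x"])
        ll = self.loglik(psi, res)
        theta = res.x[: self.kf]
        b = res.x[self.kf :].reshape(self.ns, 2)
        return theta, b, psi, ll, bool(res.success)


def _fit_nonlinear_mixed(wtp: pd.DataFrame, spec: BundleModelSpec) -> BundleModelFit:
    fam = _FAMILY_TABLE[spec.family]
    vi, vj, y, subj = _bundle_arrays(wtp)
    engine = _LaplaceNLME(fam, vi, vj, y, subj)
    theta, b, psi, ll, ok = engine.fit(spec.n_starts, spec.start_seed)
    k = len(fam.param_names) + 3  # + two RE variances + residual variance
    n = y.size
    bic = -2.0 * ll + k * np.log(n)
    fitted = engine._predict_rows(theta, b)
    rss = float(((y - fitted) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    re = pd.DataFrame(
        {"subject_id": engine.subjects, "u0": b[:, 0], "u1": b[:, 1]}
    )
    return BundleModelFit(
        family=spec.family, method="mixed",
        params=dict(zip(fam.param_names, theta)), se=None,
        random_effects=re, loglik=float(ll), bic=float(bic),
        r2=1.0 - rss / tss if tss > 0 else np.nan,
        n_obs=n, n_params=k, converged=ok,
        variance_components={
            "resid_sd": float(np.exp(psi[0])),
            "re_sd_intercept": float(np.exp(psi[1])),
            "re_sd_slope": float(np.exp(psi[2])),
        },
    )


def fit_bundle_model(wtp: pd.DataFrame, spec: BundleModelSpec) -> BundleModelFit:
    """Fit one family, with subject random effects where the data allow.

    A single-subject dataset (or ``spec.random_effects=False``) falls back
    to the pooled fixed-effects fit; the linear family uses the exact
    linear-mixed-model likelihood, the nonlinear families a Laplace
    approximation.
    """
    n_subj = wtp.subject_id.nunique()
    if not spec.random_effects:
        return fit_fixed_effects(wtp, spec)
    if n_subj < 2:
        warnings.warn("single subject: falling back to fixed-effects fit")
        return fit_fixed_effects(wtp, spec)
    if spec.family == "linear":
        return _fit_linear_mixed(wtp)
    return _fit_nonlinear_mixed(wtp, spec)


def compare_bundle_models(
    wtp: pd.DataFrame,
    families: list[str] = list(FAMILIES),
    include_mixed: bool = False,
    rank_by: str = "bic_summed",
    n_starts: int = 5,
) -> pd.DataFrame:
    """Model comparison across families.

    Always reports the summed per-participant BIC (the headline metric);
    ``include_mixed=True`` adds the mixed-model BIC. ``delta_bic`` is
    relative to the best (lowest) model on ``rank_by``; non-converged
    families are flagged and excluded from the ranking.
    """
    if len(families) < 2:
        raise ValueError("need at least two families to compare")
    rows = []
    for famname in families:
        spec = BundleModelSpec(family=famname, n_starts=n_starts)
        per = fit_per_subject(wtp, spec)
        row = {
            "family": famname,
            "bic_summed": per.bic,
            "r2": per.r2,
            "converged": per.converged,
        }
        if include_mixed:
            mixed = fit_bundle_model(wtp, spec)
            row["bic_mixed"] = mixed.bic
            row["r2_mixed"] = mixed.r2
            row["converged"] = row["converged"] and mixed.converged
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table.converged
    best = table.loc[ok, rank_by].min() if ok.any() else np.nan
    table["delta_bic"] = np.where(ok, table[rank_by] - best, np.nan)
    return table.sort_values("delta_bic").reset_index(drop=True)


def fit_by_bundle_type(
    wtp: pd.DataFrame, strata: tuple[str, ...] | None = None
) -> dict[str, BundleModelFit]:
    """Linear fits stratified by bundle type (food, trinket, mixed, same_item).

    Fits every stratum present in the data, or exactly ``strata`` if given
    (an empty requested stratum raises an error naming it). Same-item
    bundles have vi = vj, so the two slopes are unidentifiable separately;
    the stratum is fitted as b0 + c*(vi+vj) with fixed effects only and
    both slopes reported as c.
    """
    fits: dict[str, BundleModelFit] = {}
    present = set(wtp.loc[wtp.trial_type == "bundle", "bundle_type"].dropna())
    if strata is not None:
        missing = [s for s in strata if s not in present]
        if missing:
            raise FitError(f"empty bundle-type stratum: {missing[0]}")
        present = set(strata)
    for btype in sorted(present):
        sub = wtp[(wtp.trial_type != "bundle") | (wtp.bundle_type == btype)]
        if btype == "same_item":
            vi, vj, y, _ = _bundle_arrays(sub)
            X = np.column_stack([np.ones_like(vi), vi + vj])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(((y - X @ coef) ** 2).sum())
            tss = float(((y - y.mean()) ** 2).sum())
            ll, bic, k = _gaussian_ml_stats(rss, y.size, 2)
            fits[btype] = BundleModelFit(
                family="linear", method="fixed",
                params={"beta0": float(coef[0]), "beta1": float(coef[1]),
                        "beta2": float(coef[1])},
                se=None, random_effects=None, loglik=ll, bic=bic,
                r2=1.0 - rss / tss if tss > 0 else np.nan,
                n_obs=y.size, n_params=k, converged=True,
            )
        else:
            n_subj = sub.subject_id.nunique()
            spec = BundleModelSpec(family="linear", random_effects=n_subj >= 2)
            fits[btype] = fit_bundle_model(sub, spec)
    return fits


def evaluate_fit_curve(
    fit: BundleModelFit, v_max: float = 10.0, step: float = 0.01
) -> pd.DataFrame:
    """Predicted bundle value along the equal-member diagonal vi = vj.

    The grid runs the common member value from 0 to ``v_max`` in ``step``
    increments (1001 points by default); the x-axis is the summed item
    value, i.e. twice the common value.
    """
    if not fit.converged:
        raise FitError("cannot evaluate a non-converged fit")
    v = np.arange(0.0, v_max + step / 2, step)
    pred = fit.predict(v, v)
    return pd.DataFrame({"sum_value": 2.0 * v, "predicted_bundle_value": pred})
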