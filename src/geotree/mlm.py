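"""Cross-classified random-intercepts model and the global linear baseline.

Model
-----
For country i belonging simultaneously to income type t and development
stage s (two non-nested grouping factors):

    y_i(t,s) = beta0 + beta' x_i + u_t + u_s + e_i(t,s)
    u_t ~ N(0, sigma2_t),  u_s ~ N(0, sigma2_s),  e ~ N(0, sigma2_e)

Estimation is restricted maximum likelihood (REML), preferred over ML here
because the factors have very few levels (4 and 6), where ML variance
components are badly biased. The marginal covariance is

    V = sigma2_t Z_t Z_t' + sigma2_s Z_s Z_s' + sigma2_e I.

Writing gamma_f = sigma2_f / sigma2_e and W = I + sum_f gamma_f Z_f Z_f',
sigma2_e profiles out analytically and the REML criterion is optimized over
log gamma (non-negativity by construction) by Nelder-Mead from three fixed
starts, keeping the best — deterministic given the data. All linear algebra
uses the Woodbury identity through the q = (#levels) cross-product matrices,
so each criterion evaluation costs O(q^3) regardless of n.

Fixed effects come from generalized least squares at the optimum; random
effects are predicted by their BLUPs u_hat = gamma_f Z_f' W^{-1} (y - X b),
which shrink group means toward zero. Prediction for a new observation adds
the BLUPs of its groups; an unseen group level contributes 0 (its prior
mean), with a logged notice.

With 4 and 6 levels the variance components are weakly identified; the
results object therefore exposes profile-likelihood support intervals
(`profile_interval`) and flags boundary estimates rather than failing.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.stats

logger = logging.getLogger(__name__)

_LOG_GAMMA_BOUNDS = (-20.0, 12.0)
_STARTS = ((-4.0, -4.0), (0.0, 0.0), (2.0, 2.0))


@dataclasses.dataclass(frozen=True)
class CrossClassifiedSpec:
    """Columns defining the model: response ~ covariates + (1|factor_a) + (1|factor_b)."""

    response: str
    covariates: tuple[str, ...]
    factor_a: str = "income_type"
    factor_b: str = "stage"

    def __post_init__(self) -> None:
        if self.response in self.covariates:
            raise ValueError("response cannot be one of the covariates")
        if self.factor_a == self.factor_b:
            raise ValueError("the two classification factors must be distinct")


DEFAULT_COVARIATES = ("log_gdp_per_capita", "urbanization_rate", "neonatal_mortality")


def design_frame(panel_df: pd.DataFrame, assignments: pd.DataFrame | None = None) -> pd.DataFrame:
    """Merge a panel with its tree assignments and add log GDP per capita.

    Convenience for building the default model frame: the three development
    indicators are the forecastable covariates, with GDP entering on the log
    scale (income effects on mortality are multiplicative in income).
    """
    df = panel_df.copy()
    if assignments is not None:
        df = df.merge(assignments, on="country_id", how="inner", validate="1:1")
    df["log_gdp_per_capita"] = np.log(df["gdp_per_capita"])
    return df


class _RemlCore:
    """Profiled REML for y = X b + sum_f Z_f u_f + e via cross-products."""

    def __init__(self, y: np.ndarray, X: np.ndarray, z_codes: list[np.ndarray],
                 z_sizes: list[int]):
        self.n, self.p = X.shape
        self.y, self.X = y, X
        self.z_codes, self.z_sizes = z_codes, z_sizes
        self.offsets = np.concatenate(([0], np.cumsum(z_sizes)))
        self.q = int(self.offsets[-1])
        Z = np.zeros((self.n, self.q))
        for f, codes in enumerate(z_codes):
            Z[np.arange(self.n), self.offsets[f] + codes] = 1.0
        self.Z = Z
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ X
        self.Zty = Z.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def _gamma_vec(self, gammas: np.ndarray) -> np.ndarray:
        g = np.empty(self.q)
        for f, gf in enumerate(gammas):
            g[self.offsets[f]:self.offsets[f + 1]] = gf
        return g

    def _solve(self, gammas: np.ndarray):
        """Return (beta, XtWiX, rWr, logdetW, XtWiX_logdet)."""
        g = self._gamma_vec(gammas)
        rg = np.sqrt(g)
        S = np.eye(self.q) + (rg[:, None] * self.ZtZ) * rg[None, :]
        cS, low = scipy.linalg.cho_factor(S, lower=True)
        logdetW = 2.0 * float(np.sum(np.log(np.diag(cS))))

        def wi_quad(A_zt, B_zt, AtB):
            # A' W^{-1} B = A'B - (Z'A)' rg S^{-1} rg (Z'B)
            t = scipy.linalg.cho_solve((cS, low), rg[:, None] * B_zt)
            return AtB - (rg[:, None] * A_zt).T @ t

        XtWiX = wi_quad(self.ZtX, self.ZtX, self.XtX)
        XtWiy = wi_quad(self.ZtX, self.Zty[:, None], self.Xty[:, None])[:, 0]
        ytWiy = float(wi_quad(self.Zty[:, None], self.Zty[:, None],
                              np.array([[self.yty]]))[0, 0])
        cX, lowX = scipy.linalg.cho_factor(XtWiX, lower=True)
        beta = scipy.linalg.cho_solve((cX, lowX), XtWiy)
        logdetXtWiX = 2.0 * float(np.sum(np.log(np.diag(cX))))
        rWr = max(ytWiy - float(XtWiy @ beta), 1e-300)
        return beta, XtWiX, rWr, logdetW, logdetXtWiX

    def neg_reml(self, log_gammas: np.ndarray) -> float:
        gammas = np.exp(np.clip(log_gammas, *_LOG_GAMMA_BOUNDS))
        try:
            _, _, rWr, logdetW, logdetXtWiX = self._solve(gammas)
        except np.linalg.LinAlgError:
            return np.inf
        n, p = self.n, self.p
        sigma2_e = rWr / (n - p)
        ll = -0.5 * (
            (n - p) * (np.log(2.0 * np.pi * sigma2_e) + 1.0)
            + logdetW
            + logdetXtWiX
        )
        return -ll

    def blups(self, gammas: np.ndarray, beta: np.ndarray) -> list[np.ndarray]:
        g = self._gamma_vec(gammas)
        rg = np.sqrt(g)
        S = np.eye(self.q) + (rg[:, None] * self.ZtZ) * rg[None, :]
        r_zt = self.Zty - self.ZtX @ beta  # Z'(y - X beta)
        # Z' W^{-1} r = Z'r - Z'Z rg S^{-1} rg Z'r
        t = scipy.linalg.cho_solve(scipy.linalg.cho_factor(S, lower=True),
                                   rg * r_zt)
        ztwir = r_zt - self.ZtZ @ (rg * t)
        u = g * ztwir
        return [u[self.offsets[f]:self.offsets[f + 1]] for f in range(len(self.z_sizes))]


class CrossClassifiedMLM:
    """Cross-classified random-intercepts model (statsmodels-style).

    Parameters
    ----------
    endog : response vector.
    exog : covariate matrix WITHOUT constant (one is added, named "const").
    factor_a, factor_b : group label vectors (income type, development stage).
    """

    def __init__(self, endog, exog, factor_a, factor_b,
                 exog_names=None, factor_names=("income_type", "stage")):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        keep = ~np.isnan(y)
        if not keep.all():
            logger.info("dropping %d rows with missing response", int((~keep).sum()))
        y, X = y[keep], X[keep]
        fa = np.asarray(factor_a, dtype=object).ravel()[keep]
        fb = np.asarray(factor_b, dtype=object).ravel()[keep]
        if np.isnan(X).any():
            raise ValueError("missing covariate values")
        self.levels_a, codes_a = np.unique(fa, return_inverse=True)
        self.levels_b, codes_b = np.unique(fb, return_inverse=True)
        if len(self.levels_a) < 2 or len(self.levels_b) < 2:
            raise ValueError("each classification factor needs >= 2 observed levels")
        Xc = np.column_stack([np.ones(len(y)), X])
        if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
            raise ValueError("singular fixed-effects design")
        if len(y) <= Xc.shape[1] + 3:
            raise ValueError("too few observations for the fixed-effects design")
        names = list(exog_names) if exog_names is not None else [
            f"x{j}" for j in range(1, X.shape[1] + 1)
        ]
        self.exog_names = ["const"] + names
        self.factor_names = tuple(factor_names)
        self._core = _RemlCore(
            y, Xc, [codes_a, codes_b], [len(self.levels_a), len(self.levels_b)]
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, spec: CrossClassifiedSpec) -> "CrossClassifiedMLM":
        cols = [spec.response, *spec.covariates, spec.factor_a, spec.factor_b]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        sub = df.dropna(subset=[*spec.covariates, spec.factor_a, spec.factor_b])
        return cls(
            sub[spec.response],
            sub[list(spec.covariates)],
            sub[spec.factor_a],
            sub[spec.factor_b],
            exog_names=list(spec.covariates),
            factor_names=(spec.factor_a, spec.factor_b),
        )

    def fit(self, starts=_STARTS, xatol: float = 1e-5, fatol: float = 1e-7,
            maxiter: int = 2000) -> "CrossClassifiedMLMResults":
        """Maximize the REML criterion from each fixed start; keep the best."""
        core = self._core
        best = None
        start_values = []
        for s in starts:
            res = scipy.optimize.minimize(
                core.neg_reml, np.asarray(s, dtype=float), method="Nelder-Mead",
                options={"xatol": xatol, "fatol": fatol, "maxiter": maxiter},
            )
            start_values.append(-core.neg_reml(np.asarray(s, dtype=float)))
            if best is None or res.fun < best.fun:
                best = res
        log_g = np.clip(best.x, *_LOG_GAMMA_BOUNDS)
        gammas = np.exp(log_g)
        # snap numerically-zero ratios to the boundary
        gammas[log_g <= _LOG_GAMMA_BOUNDS[0] + 1e-6] = 0.0
        beta, XtWiX, rWr, _, _ = core._solve(np.maximum(gammas, 0.0))
        sigma2_e = rWr / (core.n - core.p)
        cov_beta = sigma2_e * np.linalg.inv(XtWiX)
        u_a, u_b = core.blups(gammas, beta)
        return CrossClassifiedMLMResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            cov_params=pd.DataFrame(cov_beta, index=self.exog_names, columns=self.exog_names),
            var_type=float(gammas[0] * sigma2_e),
            var_stage=float(gammas[1] * sigma2_e),
            var_resid=float(sigma2_e),
            blups_type=pd.Series(u_a, index=self.levels_a),
            blups_stage=pd.Series(u_b, index=self.levels_b),
            reml_criterion=float(-best.fun),
            start_criteria=tuple(start_values),
            converged=bool(best.success),
            n_obs=int(core.n),
            _log_gammas=tuple(np.where(gammas > 0, np.log(np.maximum(gammas, 1e-300)),
                                       -np.inf)),
        )


@dataclasses.dataclass
class CrossClassifiedMLMResults:
    """REML fit: fixed effects, variance components, BLUPs, diagnostics."""

    model: CrossClassifiedMLM
    params: pd.Series
    cov_params: pd.DataFrame
    var_type: float
    var_stage: float
    var_resid: float
    blups_type: pd.Series
    blups_stage: pd.Series
    reml_criterion: float
    start_criteria: tuple
    converged: bool
    n_obs: int
    _log_gammas: tuple = (0.0, 0.0)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = scipy.stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse, "upper": self.params + z * self.bse}
        )

    def predict(self, newdata: pd.DataFrame) -> np.ndarray:
        """Fixed part + BLUPs of the observation's groups.

        ``newdata`` must carry the covariate and factor columns the model was
        built from (via ``from_dataframe``); an unseen factor level
        contributes 0 — the population-level prediction — with a logged
        notice.
        """
        cov_names = self.params.index[1:]
        missing = [c for c in cov_names if c not in newdata.columns]
        if missing:
            raise ValueError(f"missing covariate columns in newdata: {missing}")
        X = newdata[list(cov_names)].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise ValueError("missing covariate values in newdata")
        yhat = self.params.iloc[0] + X @ self.params.iloc[1:].to_numpy()
        fa, fb = self.model.factor_names
        for col, blups in ((fa, self.blups_type), (fb, self.blups_stage)):
            if col not in newdata.columns:
                raise ValueError(f"missing factor column {col!r} in newdata")
            labels = newdata[col].to_numpy()
            known = pd.Series(labels).isin(blups.index).to_numpy()
            if not known.all():
                unseen = sorted(set(labels[~known]))
                logger.info(
                    "predict: unseen %s level(s) %s -> population-level prediction",
                    col, unseen,
                )
            add = np.zeros(len(labels))
            add[known] = blups.reindex(labels[known]).to_numpy()
            yhat = yhat + add
        return np.asarray(yhat, dtype=float)

    def profile_interval(self, component: str, level: float = 0.95,
                         grid: int = 200) -> tuple[float, float]:
        """Profile-REML support interval for a variance component.

        ``component`` is "type" or "stage". The interval is the set of values
        whose profiled criterion lies within chi2_1(level)/2 of the maximum;
        a lower end at 0 indicates the component is compatible with absence.
        """
        f = {"type": 0, "stage": 1}[component]
        core = self.model._core
        drop = scipy.stats.chi2.ppf(level, df=1) / 2.0
        base = self.reml_criterion
        cur = list(self._log_gammas)
        lo_b, hi_b = _LOG_GAMMA_BOUNDS

        def crit(lg: float) -> float:
            x = list(cur)
            x[f] = lg

            def inner(other_lg):
                xx = list(x)
                xx[1 - f] = other_lg[0]
                return core.neg_reml(np.asarray(xx))

            r = scipy.optimize.minimize_scalar(
                lambda o: inner([o]), bounds=(lo_b, hi_b), method="bounded"
            )
            return -r.fun

        lgs = np.linspace(lo_b, hi_b, grid)
        vals = np.array([crit(lg) for lg in lgs])
        ok = vals >= base - drop - 1e-9
        if not ok.any():
            return (0.0, np.inf)
        sigma2 = np.exp(lgs[ok]) * self.var_resid
        lower = 0.0 if ok[0] else float(sigma2.min())
        upper = np.inf if ok[-1] else float(sigma2.max())
        return (lower, upper)

    def summary(self) -> str:
        lines = [
            "Cross-classified random-intercepts model (REML)",
            "=" * 58,
            f"No. observations: {self.n_obs}    converged: {self.converged}",
            f"REML criterion:   {self.reml_criterion:.4f}",
            "",
            f"{'coef':<22}{'estimate':>12}{'std err':>12}{'z':>9}",
            "-" * 58,
        ]
        for name in self.params.index:
            b, se = self.params[name], self.bse[name]
            z = b / se if se > 0 else np.nan
            lines.append(f"{name:<22}{b:>12.4f}{se:>12.4f}{z:>9.2f}")
        fa, fb = self.model.factor_names
        lines += [
            "-" * 58,
            f"var({fa})".ljust(30) + f"{self.var_type:>12.4f}",
            f"var({fb})".ljust(30) + f"{self.var_stage:>12.4f}",
            "var(residual)".ljust(30) + f"{self.var_resid:>12.4f}",
            "-" * 58,
            f"BLUPs {fa}: "
            + ", ".join(f"{k}={v:.2f}" for k, v in self.blups_type.items()),
            f"BLUPs {fb}: "
            + ", ".join(f"{k}={v:.2f}" for k, v in self.blups_stage.items()),
        ]
        if min(len(self.blups_type), len(self.blups_stage)) <= 6:
            lines.append(
                "note: few group levels -> variance components weakly identified; "
                "see profile_interval()."
            )
        return "\n".join(lines)

    def plot_blups(self, ax=None):
        """Dot plot of the estimated group effects (both factors)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        fa, fb = self.model.factor_names
        labels = [f"{fa}:{k}" for k in self.blups_type.index] + [
            f"{fb}:{k}" for k in self.blups_stage.index
        ]
        vals = np.concatenate([self.blups_type.to_numpy(), self.blups_stage.to_numpy()])
        ax.axvline(0.0, color="grey", lw=0.8)
        ax.plot(vals, np.arange(len(vals)), "o")
        ax.set_yticks(np.arange(len(vals)), labels)
        ax.set_xlabel("estimated group effect (BLUP)")
        return ax

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "var_type": self.var_type,
            "var_stage": self.var_stage,
            "var_resid": self.var_resid,
            "blups_type": {str(k): float(v) for k, v in self.blups_type.items()},
            "blups_stage": {str(k): float(v) for k, v in self.blups_stage.items()},
            "reml_criterion": self.reml_criterion,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "factor_names": list(self.model.factor_names),
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclasses.dataclass(frozen=True)
class MLMPredictor:
    """Lightweight deserialized fit sufficient for prediction."""

    params: pd.Series
    blups_type: pd.Series
    blups_stage: pd.Series
    factor_names: tuple[str, str]
    var_type: float = 0.0
    var_stage: float = 0.0
    var_resid: float = 1.0
    converged: bool = True

    predict = CrossClassifiedMLMResults.predict

    @property
    def model(self):  # predict() reads .model.factor_names
        return _Names(self.factor_names)


class _Names:
    def __init__(self, factor_names):
        self.factor_names = factor_names


def load_fit(path: str | Path) -> MLMPredictor:
    """Load a serialized fit for prediction (params, BLUPs, factor names)."""
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    blups_stage = pd.Series(d["blups_stage"])
    # stage levels serialize as strings; restore integers where possible
    try:
        blups_stage.index = blups_stage.index.astype(int)
    except (TypeError, ValueError):
        pass
    return MLMPredictor(
        params=pd.Series(d["params"]),
        blups_type=pd.Series(d["blups_type"]),
        blups_stage=blups_stage,
        factor_names=tuple(d["factor_names"]),
        var_type=d["var_type"],
        var_stage=d["var_stage"],
        var_resid=d["var_resid"],
        converged=d["converged"],
    )


def fit_crossed_mlm(df: pd.DataFrame, spec: CrossClassifiedSpec) -> CrossClassifiedMLMResults:
    """Convenience: build and fit the cross-classified model from a frame."""
    return CrossClassifiedMLM.from_dataframe(df, spec).fit()


def fit_lm(df: pd.DataFrame, spec: CrossClassifiedSpec):
    """Global linear baseline: OLS with the same covariates, no group effects."""
    import statsmodels.api as sm

    sub = df.dropna(subset=[spec.response, *spec.covariates])
    X = sm.add_constant(sub[list(spec.covariates)].to_numpy(dtype=float),
                        has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design in linear baseline")
    res = sm.OLS(sub[spec.response].to_numpy(dtype=float), X).fit()
    return _LMWrapper(res, spec)


class _LMWrapper:
    """OLS baseline with the same predict() surface as the MLM results."""

    def __init__(self, results, spec: CrossClassifiedSpec):
        self.results = results
        self.spec = spec
        self.params = pd.Series(
            results.params, index=["const", *spec.covariates]
        )

    def predict(self, newdata: pd.DataFrame) -> np.ndarray:
        X = newdata[list(self.spec.covariates)].to_numpy(dtype=float)
        return self.params.iloc[0] + X @ self.params.iloc[1:].to_numpy()

    @property
    def resid_var(self) -> float:
        return float(self.results.mse_resid)


def _r2_pair(obs: np.ndarray, pred: np.ndarray) -> tuple[float, float]:
    """(squared Pearson correlation, 1 - SSE/SST)."""
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    r = np.corrcoef(obs, pred)[0, 1]
    sse = float(np.sum((obs - pred) ** 2))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    return float(r * r), 1.0 - sse / sst


def holdout_evaluate(
    df: pd.DataFrame,
    spec: CrossClassifiedSpec,
    train_fraction: float = 0.7,
    seed: int | None = 0,
    max_attempts: int = 20,
) -> dict:
    """70/30 hold-out comparison of the MLM against the linear baseline.

    The split is random, stratified by ``factor_a`` (so no income branch
    empties out); both models are fitted on the training rows and R^2 is the
    squared Pearson correlation of predicted vs observed on the hold-out
    (1 - SSE/SST is reported alongside). If a draw leaves either factor with
    fewer than two training levels it is re-drawn up to ``max_attempts``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    data = df.dropna(subset=[spec.response, *spec.covariates,
                             spec.factor_a, spec.factor_b]).reset_index(drop=True)
    rng = np.random.default_rng(seed)
    for attempt in range(max_attempts):
        train_idx = []
        for _, grp in data.groupby(spec.factor_a):
            idx = rng.permutation(grp.index.to_numpy())
            n_train = int(round(train_fraction * len(idx)))
            n_train = min(max(n_train, 1), len(idx) - 1) if len(idx) > 1 else len(idx)
            train_idx.extend(idx[:n_train])
        train_mask = np.zeros(len(data), dtype=bool)
        train_mask[np.asarray(train_idx, dtype=int)] = True
        train, test = data[train_mask], data[~train_mask]
        if (train[spec.factor_a].nunique() >= 2 and train[spec.factor_b].nunique() >= 2
                and len(test) >= 3):
            break
    else:
        raise ValueError("could not draw a training split retaining both factors")

    mlm_res = fit_crossed_mlm(train, spec)
    lm_res = fit_lm(train, spec)
    obs = test[spec.response].to_numpy(dtype=float)
    pred_mlm = mlm_res.predict(test)
    pred_lm = lm_res.predict(test)
    r2_mlm, r2_mlm_sse = _r2_pair(obs, pred_mlm)
    r2_lm, r2_lm_sse = _r2_pair(obs, pred_lm)
    return {
        "r2_mlm": r2_mlm,
        "r2_lm": r2_lm,
        "r2_mlm_sse": r2_mlm_sse,
        "r2_lm_sse": r2_lm_sse,
        "n_train": int(len(train)),
        "n_test": int(len(test)),
        "seed": seed,
        "mlm": mlm_res,
        "lm": lm_res,
    }
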