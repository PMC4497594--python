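"""Model evaluation: errors, exclusion rule, goodness of fit, model choice.

The per-route error of a model is log(observed) - log(predicted), computed
where both are positive.  Under the working assumption that these errors are
standard normal, routes with |error| > 2 are flagged as poorly described; a
route flagged under *both* models is "unmodelable".  Fit quality is
summarised by the percent reduction in Poisson deviance, an adjusted R^2 of
log observed on log predicted, Sorensen-Dice per-route overlap, and
prediction/observation ratio summaries.  Finally, a logistic regression of
the per-route winner on the gravity factor gm = pop_i*pop_j/d gives a simple
rule for choosing between the two models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import fit_gravity, gravity_factor, poisson_deviance, reduction_in_deviance

__all__ = [
    "RouteErrors",
    "FitReport",
    "ChoiceModel",
    "route_errors",
    "flag_unmodelable",
    "ks_normality",
    "fit_statistics",
    "label_better_model",
    "fit_choice_logistic",
    "subset_analysis",
]


@dataclass
class RouteErrors:
    """Per-route log errors for one model, with zero-flow bookkeeping."""

    model: str
    table: pd.DataFrame  # origin_id, dest_id, observed, predicted, error
    n_zero_observed: int
    n_zero_predicted: int


@dataclass
class FitReport:
    model: str
    n_routes: int
    n_parameters: int
    reduction_in_deviance_pct: float
    adjusted_r2: float
    sse_log: float
    dice_mean: float
    dice_per_route: pd.Series = field(repr=False, default=None)
    ratio_pred_over_obs: dict | None = None
    ratio_obs_over_pred: dict | None = None
    n_zero_observed: int = 0

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "n_routes": self.n_routes,
            "n_parameters": self.n_parameters,
            "reduction_in_deviance_pct": self.reduction_in_deviance_pct,
            "adjusted_r2": self.adjusted_r2,
            "sse_log": self.sse_log,
            "dice_mean": self.dice_mean,
            "ratio_pred_over_obs": self.ratio_pred_over_obs,
            "ratio_obs_over_pred": self.ratio_obs_over_pred,
            "n_zero_observed": self.n_zero_observed,
        }
        return d


@dataclass
class ChoiceModel:
    b0: float
    b1: float
    conf_int: dict[str, tuple[float, float]]
    pseudo_r2: float
    transform: str
    winners: pd.DataFrame = field(repr=False, default=None)
    binned_win_rates: pd.DataFrame = field(repr=False, default=None)
    separation: bool = False


def route_errors(od: pd.DataFrame, predicted: np.ndarray, model: str = "model") -> RouteErrors:
    """error = log(observed) - log(predicted) on routes where both are positive."""
    obs = od["trips"].to_numpy(dtype=float)
    pred = np.asarray(predicted, dtype=float)
    ok = (obs > 0) & (pred > 0)
    tab = od.loc[ok, ["origin_id", "dest_id"]].copy()
    tab["observed"] = obs[ok]
    tab["predicted"] = pred[ok]
    tab["error"] = np.log(obs[ok]) - np.log(pred[ok])
    return RouteErrors(
        model=model,
        table=tab.reset_index(drop=True),
        n_zero_observed=int((obs <= 0).sum()),
        n_zero_predicted=int((pred <= 0).sum()),
    )


def flag_unmodelable(
    errors_by_model: dict[str, RouteErrors], rule: str = "fixed", z: float = 2.0
) -> pd.DataFrame:
    """Apply the 2-SD exclusion rule per model; unmodelable = flagged by all.

    ``rule="fixed"`` takes the N(0,1) assumption literally (flag |e| > z);
    ``rule="empirical"`` flags outside mean +/- z*SD of each model's errors.
    Returns one row per route present for every model, with per-model flags
    and the combined ``unmodelable`` column.
    """
    if rule not in ("fixed", "empirical"):
        raise ValueError("rule must be 'fixed' or 'empirical'")
    merged: pd.DataFrame | None = None
    for name, re_ in errors_by_model.items():
        t = re_.table[["origin_id", "dest_id", "error"]].rename(columns={"error": f"error_{name}"})
        merged = t if merged is None else merged.merge(t, on=["origin_id", "dest_id"], how="inner")
    flags = []
    for name in errors_by_model:
        e = merged[f"error_{name}"]
        if rule == "fixed":
            flag = e.abs() > z
        else:
            flag = (e - e.mean()).abs() > z * e.std(ddof=1)
        merged[f"flagged_{name}"] = flag
        flags.append(flag)
    merged["unmodelable"] = np.logical_and.reduce(flags)
    return merged


def ks_normality(errors: np.ndarray) -> tuple[float, float]:
    """One-sample KS test of the errors against the standard normal N(0,1)."""
    from scipy import stats

    errors = np.asarray(errors, dtype=float)
    if len(errors) < 10:
        raise ValueError("need at least 10 errors for the KS diagnostic")
    res = stats.kstest(errors, "norm", args=(0.0, 1.0))
    return float(res.statistic), float(res.pvalue)


def fit_statistics(
    od: pd.DataFrame, predicted: np.ndarray, model: str, n_parameters: int
) -> FitReport:
    """Goodness-of-fit summary for one model's predictions on an OD table.

    Reduction in deviance is relative to the intercept-only (grand-mean)
    Poisson model, so it applies to fitted and parameter-free models alike.
    Adjusted R^2 comes from the OLS of log observed on log predicted over
    positive routes, adjusted for ``n_parameters``.  Dice and ratio summaries
    are also restricted to positive observed (and predicted) routes; zero
    flows are reported as counts.
    """
    obs = od["trips"].to_numpy(dtype=float)
    pred = np.asarray(predicted, dtype=float)
    red = reduction_in_deviance(obs, pred)

    ok = (obs > 0) & (pred > 0)
    lo, lp = np.log(obs[ok]), np.log(pred[ok])
    n = int(ok.sum())
    if n > n_parameters + 1 and lp.std() > 0:
        r = np.corrcoef(lo, lp)[0, 1]
        r2 = r * r
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - n_parameters - 1)
    else:
        adj = float("nan")
    sse_log = float(np.sum((lo - lp) ** 2))

    dice = 2.0 * np.minimum(obs[ok], pred[ok]) / (obs[ok] + pred[ok])
    po = pred[ok] / obs[ok]
    op = obs[ok] / pred[ok]

    def _summ(x: np.ndarray) -> dict:
        return {
            "mean": float(np.mean(x)),
            "q2.5": float(np.quantile(x, 0.025)),
            "q97.5": float(np.quantile(x, 0.975)),
        }

    routes = od[["origin_id", "dest_id"]].astype(str).agg("->".join, axis=1)
    return FitReport(
        model=model,
        n_routes=len(od),
        n_parameters=n_parameters,
        reduction_in_deviance_pct=float(red),
        adjusted_r2=float(adj),
        sse_log=sse_log,
        dice_mean=float(np.mean(dice)),
        dice_per_route=pd.Series(dice, index=routes[ok]),
        ratio_pred_over_obs=_summ(po),
        ratio_obs_over_pred=_summ(op),
        n_zero_observed=int((obs <= 0).sum()),
    )


def label_better_model(
    flags: pd.DataFrame, model_a: str = "gravity", model_b: str = "radiation"
) -> pd.DataFrame:
    """Per-route winner: the model with the smaller |error|; ties go to ``model_a``.

    Only non-unmodelable routes are labelled.  ``flags`` is the output of
    :func:`flag_unmodelable` for the two models.
    """
    ok = flags[~flags["unmodelable"]].copy()
    ea = ok[f"error_{model_a}"].abs()
    eb = ok[f"error_{model_b}"].abs()
    ok["winner"] = np.where(ea <= eb, model_a, model_b)
    return ok


def fit_choice_logistic(
    winners: pd.DataFrame,
    gm: pd.Series | np.ndarray,
    positive_label: str = "gravity",
    transform: str = "log10",
    n_bins: int = 8,
) -> ChoiceModel:
    """Logistic regression of the per-route winner on the gravity factor.

    Fits logit(p) = b0 + b1 * X_gm, p the probability that ``positive_label``
    wins; X_gm = log10(gm) by default (gm spans many orders of magnitude) or
    the raw factor with ``transform="raw"``.  On complete separation the
    model is refit with an L2 ridge and flagged.  Binned empirical win rates
    accompany the fit.
    """
    import statsmodels.api as sm

    y = (winners["winner"] == positive_label).to_numpy(dtype=float)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 routes won by each model")
    x = np.asarray(gm, dtype=float)
    if transform == "log10":
        if (x <= 0).any():
            raise ValueError("gravity factor must be positive for the log10 transform")
        x = np.log10(x)
    elif transform != "raw":
        raise ValueError("transform must be 'log10' or 'raw'")
    X = sm.add_constant(pd.DataFrame({"x_gm": x}))

    separation = False
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", True) or np.abs(res.params).max() > 1e3:
            raise RuntimeError("suspect separation")
        params = res.params
        ci = res.conf_int()
        conf = {"b0": tuple(ci.loc["const"]), "b1": tuple(ci.loc["x_gm"])}
        llnull = res.llnull
        pseudo = 1.0 - res.llf / llnull if llnull != 0 else float("nan")
    except Exception:
        separation = True
        res = sm.Logit(y, X).fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
        params = res.params
        conf = {"b0": (np.nan, np.nan), "b1": (np.nan, np.nan)}
        pseudo = float("nan")

    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1))
    qs[0] -= 1e-9
    bins = pd.cut(x, np.unique(qs))
    binned = (
        pd.DataFrame({"bin": bins, "win": y})
        .groupby("bin", observed=True)
        .agg(n=("win", "size"), win_rate=("win", "mean"))
        .reset_index()
    )
    binned["x_mid"] = binned["bin"].map(lambda b: b.mid).astype(float)
    return ChoiceModel(
        b0=float(params["const"]),
        b1=float(params["x_gm"]),
        conf_int={k: (float(a), float(b)) for k, (a, b) in conf.items()},
        pseudo_r2=float(pseudo),
        transform=transform,
        winners=winners,
        binned_win_rates=binned,
        separation=separation,
    )


def subset_analysis(
    od: pd.DataFrame,
    subsets: dict[str, np.ndarray],
    distance_cols: list[str],
    min_routes: int = 5,
) -> pd.DataFrame:
    """Refit the gravity model per route subset and distance measure.

    ``subsets`` maps a label to a boolean mask over ``od`` rows (e.g. routes
    touching the capital, rural-rural routes, a distance band).  Emits one
    row per (subset, distance measure) with the refitted exponents and the
    reduction in deviance; subsets with fewer than ``min_routes`` routes are
    skipped with a warning.
    """
    import warnings

    rows = []
    for label, mask in subsets.items():
        sub = od[np.asarray(mask, dtype=bool)]
        if len(sub) < min_routes:
            warnings.warn(f"subset {label!r} has {len(sub)} routes (<{min_routes}); skipped", stacklevel=2)
            continue
        for dcol in distance_cols:
            try:
                p = fit_gravity(sub, distance_col=dcol)
            except ValueError as exc:
                warnings.warn(f"subset {label!r} / {dcol}: {exc}", stacklevel=2)
                continue
            rows.append(
                {
                    "subset": label,
                    "distance": dcol,
                    "n_routes": len(sub),
                    "alpha": p.alpha,
                    "beta": p.beta,
                    "gamma": p.gamma,
                    "log_k": p.log_k,
                    "reduction_in_deviance_pct": p.reduction_in_deviance_pct,
                }
            )
    return pd.DataFrame(rows)


def density_terciles(districts: pd.DataFrame, area_km2: pd.Series | None = None) -> pd.Series:
    """Classify districts as rural/intermediate/urban by population-density terciles.

    Without polygon areas, population itself stands in for density (the
    synthetic world's districts have comparable footprints).
    """
    dens = districts.set_index("district_id")["population"].astype(float)
    if area_km2 is not None:
        dens = dens / area_km2.reindex(dens.index)
    return pd.Series(
        pd.qcut(dens, 3, labels=["rural", "intermediate", "urban"]), index=dens.index, name="class"
    )
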