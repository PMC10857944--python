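"""Negative-binomial detection-rate models with an effort offset.

One model per species: the per-station count of independent contacts is
regressed on land-cover class (treatment-coded against a reference level,
``clearfell`` by default) and the station's human detection rate, with
``log(duration_days)`` as an offset so coefficients are log differences in
*rate* (contacts per trap-day), not in raw counts.  Station counts from short
surveys over heterogeneous habitat are almost always overdispersed, hence a
negative binomial (NB2) likelihood with the dispersion parameter theta
estimated by maximum likelihood; a Pearson-ratio diagnostic against the
matching Poisson fit is provided to justify that choice per species.

The post-fit surface mirrors the least-squares-means workflow: estimated
marginal means per land-cover level (human rate held at its across-station
mean, effort fixed at one trap-day so response-scale EMMs read as
contacts/day) and all pairwise level contrasts with Wald or Tukey-adjusted
p-values.

Design cells with zero events drive their coefficient toward minus infinity
with an exploding standard error (complete separation).  Such coefficients
are *flagged*, not regularised: the estimate and its absurd SE are reported
as-is, with ``separation`` True, so the reader can see the degeneracy.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import LAND_COVERS, SurveyDataset

__all__ = [
    "build_model_table",
    "DetectionRateModel",
    "DetectionRateResults",
    "OverdispersionCheck",
    "check_overdispersion",
    "fit_nb_glm",
    "rate_ratio",
    "emm_contrasts",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    """Raised when the NB optimiser fails to produce a usable fit."""

    def __init__(self, message: str, last_params=None):
        super().__init__(message)
        self.last_params = last_params


def build_model_table(
    contacts: pd.DataFrame,
    dataset: SurveyDataset,
    species: str,
    human_rates: pd.DataFrame,
) -> pd.DataFrame:
    """One modelling row per station: count, land cover, human rate, offset.

    ``human_rates`` is the per-station table from
    :func:`ctstia.contacts.human_detection_rates`; every station in the
    deployment table must appear in it.
    """
    dep = dataset.deployments.loc[dataset.deployments["duration_days"] > 0]
    counts = (
        contacts.loc[contacts["species"] == species]
        .groupby("station_id")
        .size()
        .reindex(dep["station_id"], fill_value=0)
    )
    hr = human_rates.set_index("station_id")["human_rate"]
    missing = sorted(set(dep["station_id"]) - set(hr.index))
    if missing:
        raise ValueError(f"stations missing from human_rates: {missing}")
    return pd.DataFrame(
        {
            "station_id": dep["station_id"].to_numpy(),
            "count": counts.to_numpy().astype(int),
            "land_cover": pd.Categorical(
                dep["land_cover"].to_numpy(), categories=LAND_COVERS
            ),
            "human_rate": hr.reindex(dep["station_id"]).to_numpy(),
            "log_duration": np.log(dep["duration_days"].to_numpy()),
        }
    )


@dataclasses.dataclass(frozen=True)
class OverdispersionCheck:
    """Pearson chi-square / residual d.f. of a Poisson fit, with a verdict."""

    ratio: float
    threshold: float
    overdispersed: bool


def check_overdispersion(poisson_results, threshold: float = 1.4) -> OverdispersionCheck:
    """Dispersion diagnostic for a fitted Poisson GLM.

    Ratio ~ 1 for equidispersed data; values well above ``threshold``
    indicate the Poisson variance assumption fails and a negative binomial
    is warranted.
    """
    if poisson_results.df_resid <= 0:
        raise ValueError("overdispersion check needs positive residual d.f.")
    ratio = float(poisson_results.pearson_chi2 / poisson_results.df_resid)
    return OverdispersionCheck(
        ratio=ratio, threshold=threshold, overdispersed=ratio > threshold
    )


def rate_ratio(coefficient: float) -> float:
    """Fold change in detection rate implied by a log-scale coefficient."""
    if not np.isfinite(coefficient):
        raise ValueError("rate_ratio needs a finite coefficient")
    return float(np.exp(coefficient))


def _design(table: pd.DataFrame, reference: str) -> tuple[pd.DataFrame, list[str]]:
    if reference not in LAND_COVERS:
        raise ValueError(f"reference {reference!r} not in {list(LAND_COVERS)}")
    levels = [reference] + [lc for lc in LAND_COVERS if lc != reference]
    lc = pd.Categorical(table["land_cover"], categories=levels)
    dummies = pd.get_dummies(lc, drop_first=True).astype(float)
    X = pd.DataFrame({"intercept": np.ones(len(table))})
    for name in levels[1:]:
        X[name] = dummies[name].to_numpy() if name in dummies else 0.0
    X["human_rate"] = table["human_rate"].to_numpy()
    return X, levels


class DetectionRateModel:
    """NB2 regression of station contact counts on land cover + human rate.

    Parameters
    ----------
    table : DataFrame
        Output of :func:`build_model_table` (or equivalent columns
        ``count, land_cover, human_rate, log_duration``).
    species : str, optional
        Label carried through to the results for reporting.
    reference : str
        Land-cover level absorbed into the intercept.
    """

    def __init__(self, table: pd.DataFrame, species: str = "", reference: str = "clearfell"):
        if (table["count"] < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.isfinite(table["log_duration"]).all():
            raise ValueError("log_duration must be finite (duration_days > 0)")
        self.table = table.reset_index(drop=True)
        self.species = species
        self.reference = reference
        self.exog, self.levels = _design(self.table, reference)
        self.endog = self.table["count"].to_numpy()
        self.offset = self.table["log_duration"].to_numpy()

    @classmethod
    def from_survey(
        cls,
        contacts: pd.DataFrame,
        dataset: SurveyDataset,
        species: str,
        human_rates: pd.DataFrame,
        reference: str = "clearfell",
    ) -> "DetectionRateModel":
        table = build_model_table(contacts, dataset, species, human_rates)
        return cls(table, species=species, reference=reference)

    def _fit_nb(self, endog, exog, offset):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.NegativeBinomial(endog, exog, offset=offset)
            try:
                res = model.fit(disp=0, maxiter=200)
            except Exception:
                res = None
            if res is None or not np.isfinite(res.params).all():
                try:
                    res = model.fit(method="bfgs", disp=0, maxiter=500)
                except Exception as exc:  # pragma: no cover - defensive
                    raise ConvergenceError(f"NB fit failed: {exc}") from exc
        if not np.isfinite(res.params).all():
            raise ConvergenceError(
                "NB fit produced non-finite parameters", last_params=res.params
            )
        with warnings.catch_warnings(), np.errstate(all="ignore"):
            warnings.simplefilter("ignore")
            try:
                res.bse, res.cov_params(), res.llf  # force lazy evaluation quietly
            except ValueError:
                pass  # no covariance at a degenerate optimum; handled downstream
        return res

    def fit(
        self,
        separation_se_threshold: float = 10.0,
        dispersion_threshold: float = 1.4,
    ) -> "DetectionRateResults":
        """Maximum-likelihood fit; returns a :class:`DetectionRateResults`.

        Predictor columns with no variation (a land-cover level with no
        stations, or an identically-zero covariate) are unidentifiable; they
        are excluded from the optimisation and reported as NaN with their
        separation flag set.
        """
        keep = [
            c for c in self.exog.columns
            if c == "intercept" or self.exog[c].nunique() > 1
        ]
        exog = self.exog[keep]
        res = self._fit_nb(self.endog, exog, self.offset)
        # intercept + offset only null, for Nagelkerke pseudo-R2
        null_exog = self.exog[["intercept"]]
        res_null = self._fit_nb(self.endog, null_exog, self.offset)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pois = sm.GLM(
                self.endog, exog, family=sm.families.Poisson(), offset=self.offset
            ).fit()
        overdispersion = check_overdispersion(pois, threshold=dispersion_threshold)
        return DetectionRateResults(
            model=self,
            _res=res,
            _res_null=res_null,
            overdispersion=overdispersion,
            separation_se_threshold=separation_se_threshold,
            fitted_columns=keep,
        )


def _nagelkerke(ll_full: float, ll_null: float, n: int) -> float:
    cox_snell = 1.0 - np.exp(2.0 / n * (ll_null - ll_full))
    max_cs = 1.0 - np.exp(2.0 / n * ll_null)
    if max_cs <= 0:
        return 0.0
    return float(np.clip(cox_snell / max_cs, 0.0, 1.0))


class DetectionRateResults:
    """Fitted detection-rate model: estimates, diagnostics, EMMs, contrasts.

    Coefficient vocabulary: the intercept is the log contacts-per-day rate in
    the reference land cover at zero human rate; each land-cover coefficient
    is a log rate difference against the reference (``exp`` of it is the fold
    change); the human-rate slope is per unit of human contacts/day.
    """

    def __init__(self, model, _res, _res_null, overdispersion, separation_se_threshold,
                 fitted_columns=None):
        self.model = model
        self._res = _res
        self._res_null = _res_null
        self.overdispersion = overdispersion
        self.separation_se_threshold = separation_se_threshold

        self.coef_names = list(model.exog.columns)
        fitted = list(fitted_columns) if fitted_columns is not None else self.coef_names
        kf = len(fitted)
        raw_params = np.asarray(_res.params, dtype=float)
        try:
            with warnings.catch_warnings(), np.errstate(all="ignore"):
                warnings.simplefilter("ignore")
                raw_bse = np.asarray(_res.bse, dtype=float)
                raw_cov = np.asarray(_res.cov_params(), dtype=float)
        except ValueError:
            # degenerate optimum (e.g. dispersion at its boundary): no Wald
            # covariance is available; report NaN rather than invent one
            raw_bse = np.full_like(raw_params, np.nan)
            raw_cov = np.full((len(raw_params), len(raw_params)), np.nan)
        self.params = pd.Series(raw_params[:kf], index=fitted).reindex(self.coef_names)
        self.bse = pd.Series(raw_bse[:kf], index=fitted).reindex(self.coef_names)
        self.alpha = float(raw_params[kf]) if len(raw_params) > kf else 0.0
        self.theta = float(1.0 / self.alpha) if self.alpha > 0 else np.inf
        with np.errstate(divide="ignore", invalid="ignore"):
            self.zvalues = self.params / self.bse
        self.pvalues = pd.Series(
            2.0 * stats.norm.sf(np.abs(self.zvalues)), index=self.coef_names
        )
        self.llf = float(_res.llf)
        self.llnull = float(_res_null.llf)
        self.nobs = int(model.exog.shape[0])
        self.pseudo_r2 = _nagelkerke(self.llf, self.llnull, self.nobs)
        self.separation_flags = pd.Series(
            (~np.isfinite(self.bse)) | (self.bse.abs() > separation_se_threshold),
            index=self.coef_names,
        )
        cov = np.full((len(self.coef_names), len(self.coef_names)), np.nan)
        idx = [self.coef_names.index(c) for c in fitted]
        cov[np.ix_(idx, idx)] = raw_cov[:kf, :kf]
        self._cov = cov

    # ------------------------------------------------------------------ table
    def coef_table(self) -> pd.DataFrame:
        """Per-predictor estimate, SE, z, p, rate ratio and separation flag."""
        with np.errstate(over="ignore"):
            rr = np.exp(self.params)
        return pd.DataFrame(
            {
                "estimate": self.params,
                "std_error": self.bse,
                "z": self.zvalues,
                "p_value": self.pvalues,
                "rate_ratio": rr,
                "separation": self.separation_flags,
            }
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "lower": self.params - z * self.bse,
                "upper": self.params + z * self.bse,
            }
        )

    # ------------------------------------------------------------------- EMMs
    def _emm_vector(self, level: str) -> np.ndarray:
        """Linear-predictor weights for one level's marginal mean.

        Human rate is held at its across-station arithmetic mean and effort at
        one trap-day (offset log(1) = 0), so the EMM is a log contacts/day.
        """
        c = np.zeros(len(self.coef_names))
        c[self.coef_names.index("intercept")] = 1.0
        if level != self.model.reference:
            c[self.coef_names.index(level)] = 1.0
        c[self.coef_names.index("human_rate")] = float(
            self.model.table["human_rate"].mean()
        )
        return c

    def _linear_combo(self, c: np.ndarray) -> tuple[float, float]:
        """Estimate and SE of ``c @ beta``, ignoring zero-weight columns so a
        dropped (unidentifiable) coefficient only poisons combinations that
        actually use it."""
        nz = c != 0.0
        est = float(c[nz] @ self.params.to_numpy()[nz])
        var = float(c[nz] @ self._cov[np.ix_(nz, nz)] @ c[nz])
        se = float(np.sqrt(var)) if var >= 0 else np.nan
        return est, se

    def emmeans(self) -> pd.DataFrame:
        """Estimated marginal mean per land-cover level, log and response scale."""
        rows = []
        for level in self.levels_in_order():
            c = self._emm_vector(level)
            est, se = self._linear_combo(c)
            rows.append(
                {
                    "land_cover": level,
                    "emmean_log": est,
                    "se": se,
                    "rate_per_day": float(np.exp(est)),
                    "separation": bool(
                        level != self.model.reference and self.separation_flags[level]
                    ),
                }
            )
        return pd.DataFrame(rows)

    def levels_in_order(self) -> list[str]:
        return list(LAND_COVERS)

    def contrasts(self, adjust: str = "none") -> pd.DataFrame:
        """All 15 pairwise land-cover EMM differences with Wald z tests.

        ``adjust='tukey'`` applies the Tukey HSD correction via the
        studentized-range distribution (asymptotic, matching the normal
        reference of the Wald z); ``'none'`` reports raw p-values.
        """
        if adjust not in ("none", "tukey"):
            raise ValueError("adjust must be 'none' or 'tukey'")
        levels = self.levels_in_order()
        k = len(levels)
        rows = []
        for i in range(k):
            for j in range(i + 1, k):
                a, b = levels[i], levels[j]
                c = self._emm_vector(a) - self._emm_vector(b)
                est, se = self._linear_combo(c)
                z = est / se if se and se > 0 else 0.0
                p = float(2.0 * stats.norm.sf(abs(z)))
                if adjust == "tukey":
                    # q = |z| * sqrt(2); large d.f. reproduces the asymptotic z
                    p_adj = float(
                        stats.studentized_range.sf(abs(z) * np.sqrt(2.0), k, 1e6)
                    )
                else:
                    p_adj = p
                flagged = bool(
                    (a != self.model.reference and self.separation_flags[a])
                    or (b != self.model.reference and self.separation_flags[b])
                )
                rows.append(
                    {
                        "level_a": a,
                        "level_b": b,
                        "estimate": est,
                        "se": se,
                        "z": z,
                        "p_value": p,
                        "adjusted_p": p_adj,
                        "adjust": adjust,
                        "unreliable": flagged,
                    }
                )
        return pd.DataFrame(rows)

    # ---------------------------------------------------------------- summary
    def summary(self) -> str:
        """Human-readable fit report (Table-2 style layout)."""
        lines = [
            f"Negative binomial detection-rate model"
            + (f" — {self.model.species}" if self.model.species else ""),
            f"  stations: {self.nobs}   reference land cover: {self.model.reference}",
            f"  theta (NB size): {self.theta:.3f}   log-likelihood: {self.llf:.2f}",
            f"  pseudo-R2 (Nagelkerke): {self.pseudo_r2:.2f}",
            f"  Poisson dispersion ratio: {self.overdispersion.ratio:.2f} "
            + (
                "(overdispersed)"
                if self.overdispersion.overdispersed
                else "(no overdispersion detected)"
            ),
            "",
            f"  {'predictor':<24}{'estimate':>10}{'std err':>10}{'p':>8}{'rate ratio':>12}",
        ]
        tab = self.coef_table()
        for name, row in tab.iterrows():
            flag = "  [separation]" if row["separation"] else ""
            lines.append(
                f"  {name:<24}{row['estimate']:>10.2f}{row['std_error']:>10.2f}"
                f"{row['p_value']:>8.3f}{row['rate_ratio']:>12.2f}{flag}"
            )
        return "\n".join(lines)


def fit_nb_glm(
    table: pd.DataFrame, species: str = "", reference: str = "clearfell", **kwargs
) -> DetectionRateResults:
    """Functional entry point: build the model from a table and fit it."""
    return DetectionRateModel(table, species=species, reference=reference).fit(**kwargs)


def emm_contrasts(results: DetectionRateResults, adjust: str = "none") -> pd.DataFrame:
    """Pairwise land-cover contrasts of a fitted model (see ``contrasts``)."""
    return results.contrasts(adjust=adjust)
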