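"""Inference for the transplantation experiment and the environmental drivers.

Two layers, mirroring the field analysis:

1. Repeated-measures linear mixed models.  Calcification or respiration is
   modelled with season, station and (optionally) the station x transplant
   interaction as fixed factors and specimen identity as a random intercept
   (the same corals are measured every season).  Models are fitted by REML
   through :mod:`statsmodels`; term tests are Wald F statistics with
   containment-style denominator degrees of freedom (between-specimen terms
   are tested against the specimen stratum, within-specimen terms against
   the residual stratum — the classical balanced-design convention, exact
   for balanced random-intercept data).  Post-hoc pairwise least-squares
   means use the Tukey studentized-range adjustment (Holm selectable).

2. Exhaustive all-subsets OLS selection over the six environmental
   predictors (mean temperature, temperature variability, pH_T, Omega_arag,
   salinity, oxygen): all 2^6 - 1 = 63 main-effects models ranked by AICc
   (small-sample corrected; plain AIC selectable), with Akaike weights and
   adjusted R^2.  The parameter count includes the residual variance, the
   convention of the R AICc tooling this mirrors.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.formula.api as smf
from statsmodels.stats.diagnostic import het_breuschpagan, lilliefors

__all__ = [
    "LMMSpec",
    "LMMResult",
    "ModelSelectionResult",
    "fit_repeated_lmm",
    "posthoc_contrasts",
    "exhaustive_subset_selection",
    "adjusted_r2",
    "residual_diagnostics",
    "shallow_native_spec",
    "transplant_spec",
    "ENV_PREDICTORS",
]

#: canonical predictor columns for the all-subsets selection
ENV_PREDICTORS = (
    "mean_temp_C",
    "temp_variability_C",
    "ph_total",
    "omega_arag",
    "salinity",
    "oxygen_umol_kg",
)


@dataclass(frozen=True)
class LMMSpec:
    """Specification of one repeated-measures mixed model."""

    response: str
    fixed_terms: tuple[str, ...]
    random_term: str = "specimen_id"
    subset_filter: Callable[[pd.DataFrame], pd.Series] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not self.fixed_terms:
            raise ValueError("at least one fixed term is required")
        if not self.random_term:
            raise ValueError("a random (specimen) term is required")

    @property
    def formula(self) -> str:
        parts = []
        for term in self.fixed_terms:
            factors = term.split(":")
            parts.append(":".join(f"C({f})" for f in factors))
        return f"{self.response} ~ " + " + ".join(parts)


def shallow_native_spec(
    response: str = "calcification_g",
    shallow_stations: Sequence[str] = ("A", "B", "C", "D", "Es", "F"),
) -> LMMSpec:
    """Preset: native corals of the shallow stations; season + station effects."""
    stations = tuple(shallow_stations)

    def _filter(df: pd.DataFrame) -> pd.Series:
        return (df["transplant"] == "native") & df["station"].isin(stations)

    return LMMSpec(
        response=response,
        fixed_terms=("season", "station"),
        subset_filter=_filter,
        label="shallow_native",
    )


def transplant_spec(
    response: str = "calcification_g",
    stations: Sequence[str] = ("A", "F", "Es", "Ed"),
) -> LMMSpec:
    """Preset: native and novel corals of the four transplantation stations."""
    st = tuple(stations)

    def _filter(df: pd.DataFrame) -> pd.Series:
        return df["station"].isin(st)

    return LMMSpec(
        response=response,
        fixed_terms=("season", "station", "station:transplant"),
        subset_filter=_filter,
        label="transplant",
    )


@dataclass
class LMMResult:
    """Fitted repeated-measures mixed model with term tests."""

    spec: LMMSpec
    fixed_effects: pd.DataFrame  # estimate, se, df, t, p per coefficient
    term_tests: pd.DataFrame  # F, num_df, den_df, p per fixed term
    group_variance: float
    residual_variance: float
    n_obs: int
    n_groups: int
    converged: bool
    _fit: object = field(repr=False, default=None)
    _data: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.group_variance < 0 or self.residual_variance < 0:
            raise ValueError("variance components must be >= 0")


def _term_slices(design_info) -> dict[str, slice]:
    return {name: design_info.term_name_slices[name] for name in design_info.term_names}


def _between_within_dfs(
    exog: np.ndarray, groups: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Containment denominator dfs and a per-column between/within flag.

    A column is 'between' if it is constant within every specimen.  The
    between stratum offers n_groups - rank(group-mean design) df, the
    within stratum n_obs - n_groups - (#within-varying rank) df.
    """
    df_frame = pd.DataFrame(exog)
    gm = df_frame.groupby(groups).transform("mean").to_numpy()
    within_part = exog - gm
    col_between = np.max(np.abs(within_part), axis=0) < 1e-8

    n_obs = exog.shape[0]
    n_groups = len(np.unique(groups))
    rank_between = np.linalg.matrix_rank(
        pd.DataFrame(exog).groupby(groups).mean().to_numpy()
    )
    rank_total = np.linalg.matrix_rank(exog)
    df_between = n_groups - rank_between
    df_within = n_obs - n_groups - (rank_total - rank_between)
    return float(df_between), float(df_within), col_between


def fit_repeated_lmm(data: pd.DataFrame, spec: LMMSpec) -> LMMResult:
    """REML fit of a random-intercept model for the repeated-measures design.

    ``data`` must carry the response column, the factor columns named in
    ``spec.fixed_terms`` and the specimen identifier.  Raises ``ValueError``
    on singular (aliased) fixed-effect designs and ``RuntimeError`` if the
    optimizer fails to converge.
    """
    df = data if spec.subset_filter is None else data[spec.subset_filter(data)]
    df = df.dropna(subset=[spec.response]).copy()
    if df.empty:
        raise ValueError("no rows left after subset filter")

    counts = df.groupby(spec.random_term).size()
    if (counts < 2).all():
        raise ValueError("repeated-measures design needs >=2 observations per specimen")

    model = smf.mixedlm(spec.formula, df, groups=df[spec.random_term])
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        names = model.exog_names
        raise ValueError(
            f"singular fixed-effect design (rank {rank} < {exog.shape[1]}); "
            f"check aliasing among terms {names}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(reml=True)
        except np.linalg.LinAlgError:
            fit = model.fit(reml=True, method="powell")
        if not fit.converged:
            fit = model.fit(reml=True, method="powell")
    if not fit.converged:
        raise RuntimeError(
            f"mixed-model optimizer did not converge: {getattr(fit, 'hist', None)}"
        )

    groups = df[spec.random_term].to_numpy()
    df_between, df_within, col_between = _between_within_dfs(exog, groups)

    params = np.asarray(fit.fe_params)
    cov = np.asarray(fit.cov_params())[: len(params), : len(params)]
    se = np.sqrt(np.diag(cov))
    col_df = np.where(col_between, max(df_between, 1.0), max(df_within, 1.0))
    tvals = params / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), col_df)
    fixed = pd.DataFrame(
        {
            "estimate": params,
            "se": se,
            "df": col_df,
            "t": tvals,
            "p": pvals,
        },
        index=model.exog_names,
    )

    design_info = model.data.design_info
    rows = []
    for name, sl in _term_slices(design_info).items():
        if name == "Intercept":
            continue
        b = params[sl]
        v = cov[sl, sl]
        q = len(b)
        fstat = float(b @ np.linalg.solve(v, b) / q)
        between = bool(np.all(col_between[sl]))
        den = max(df_between if between else df_within, 1.0)
        rows.append(
            {
                "term": name,
                "F": fstat,
                "num_df": q,
                "den_df": den,
                "stratum": "between" if between else "within",
                "p": float(stats.f.sf(fstat, q, den)),
            }
        )
    term_tests = pd.DataFrame(rows).set_index("term")

    return LMMResult(
        spec=spec,
        fixed_effects=fixed,
        term_tests=term_tests,
        group_variance=float(np.asarray(fit.cov_re)[0, 0]),
        residual_variance=float(fit.scale),
        n_obs=int(len(df)),
        n_groups=int(len(counts)),
        converged=bool(fit.converged),
        _fit=fit,
        _data=df,
    )


def posthoc_contrasts(
    result: LMMResult, factor: str, adjust: str = "tukey"
) -> pd.DataFrame:
    """All pairwise least-squares-mean contrasts for one factor.

    LS means are marginal predictions averaged over a balanced grid of the
    other factors in the model.  ``adjust`` is ``tukey`` (studentized range)
    or ``holm``.  Returns a table with one row per level pair.
    """
    fit = result._fit
    data = result._data
    design_info = fit.model.data.design_info

    factors = sorted({f for term in result.spec.fixed_terms for f in term.split(":")})
    if factor not in factors:
        raise KeyError(f"factor {factor!r} not in the fitted model ({factors})")

    levels = {f: sorted(data[f].astype(str).unique()) for f in factors}
    grid = pd.DataFrame(
        list(itertools.product(*(levels[f] for f in factors))), columns=factors
    )
    from patsy import build_design_matrices

    gx = np.asarray(build_design_matrices([design_info], grid)[0])

    params = np.asarray(fit.fe_params)
    cov = np.asarray(fit.cov_params())[: len(params), : len(params)]

    lrows = {
        lev: gx[(grid[factor] == lev).to_numpy()].mean(axis=0) for lev in levels[factor]
    }

    groups = data[result.spec.random_term].to_numpy()
    df_between, df_within, col_between = _between_within_dfs(fit.model.exog, groups)

    k = len(levels[factor])
    rows = []
    for a, b in itertools.combinations(levels[factor], 2):
        contrast = lrows[a] - lrows[b]
        est = float(contrast @ params)
        var = float(contrast @ cov @ contrast)
        se = np.sqrt(var)
        # stratum of the contrast: between-specimen unless it involves
        # within-varying columns
        involved = np.abs(contrast) > 1e-12
        between = bool(np.all(col_between[involved]))
        den = max(df_between if between else df_within, 1.0)
        tval = est / se
        rows.append(
            {
                "factor": factor,
                "level_a": a,
                "level_b": b,
                "estimate": est,
                "se": se,
                "df": den,
                "t": tval,
                "p_raw": float(2.0 * stats.t.sf(abs(tval), den)),
            }
        )
    table = pd.DataFrame(rows)
    if adjust == "tukey":
        q = np.abs(table["t"].to_numpy()) * np.sqrt(2.0)
        table["p_adj"] = stats.studentized_range.sf(q, k, table["df"].to_numpy())
    elif adjust == "holm":
        p = table["p_raw"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 0.0
        for rank_i, idx in enumerate(order):
            running = max(running, (m - rank_i) * p[idx])
            adj[idx] = min(1.0, running)
        table["p_adj"] = adj
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    table["p_adj"] = table["p_adj"].clip(0.0, 1.0)
    return table


# ----------------------------------------------------------------------
# all-subsets selection


@dataclass
class ModelSelectionResult:
    """Ranked all-subsets OLS fits with information-criterion statistics."""

    table: pd.DataFrame  # one row per subset, sorted by the criterion
    criterion: str
    n_obs: int

    def __post_init__(self) -> None:
        deltas = self.table["delta"].to_numpy()
        if abs(deltas[0]) > 1e-12:
            raise ValueError("best model must have delta = 0")
        if abs(self.table["weight"].sum() - 1.0) > 1e-8:
            raise ValueError("Akaike weights must sum to 1")

    @property
    def best_model(self) -> tuple[str, ...]:
        return tuple(self.table.iloc[0]["subset"])

    @property
    def best_coefficients(self) -> dict[str, float]:
        return dict(self.table.iloc[0]["coefficients"])


def adjusted_r2(r_squared: float, n_obs: int, n_predictors: int) -> float:
    """Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    if n_obs <= n_predictors + 1:
        raise ValueError(f"adjusted R^2 undefined for n={n_obs}, p={n_predictors}")
    return 1.0 - (1.0 - r_squared) * (n_obs - 1) / (n_obs - n_predictors - 1)


def exhaustive_subset_selection(
    data: pd.DataFrame,
    response: str,
    predictors: Sequence[str] = ENV_PREDICTORS,
    criterion: str = "aicc",
) -> ModelSelectionResult:
    """Rank every non-empty predictor subset (main effects, no interactions).

    Each subset is fitted by OLS with intercept; models are ranked by AICc
    (default) or AIC, with delta values, Akaike weights and adjusted R^2.
    Subsets too large for the sample size are skipped with a warning.
    Collinearity does not abort a fit; the design condition number is
    reported per model.
    """
    if criterion not in ("aicc", "aic"):
        raise ValueError("criterion must be 'aicc' or 'aic'")
    predictors = list(predictors)
    df = data.dropna(subset=[response, *predictors])
    y = df[response].to_numpy(dtype=float)
    n = len(y)
    if n == 0:
        raise ValueError("no complete rows for selection")

    rows = []
    for size in range(1, len(predictors) + 1):
        for subset in itertools.combinations(predictors, size):
            p = len(subset)
            k = p + 2  # coefficients + intercept + residual variance
            if n - k - 1 <= 0 or n <= p + 1:
                warnings.warn(
                    f"subset {subset} skipped: n={n} too small", stacklevel=2
                )
                continue
            x = np.column_stack([np.ones(n), df[list(subset)].to_numpy(dtype=float)])
            beta, _, rank, sv = np.linalg.lstsq(x, y, rcond=None)
            resid = y - x @ beta
            rss = float(resid @ resid)
            tss = float(np.sum((y - y.mean()) ** 2))
            sigma2 = rss / n
            llf = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
            aic = -2.0 * llf + 2.0 * k
            aicc = aic + 2.0 * k * (k + 1) / (n - k - 1)
            r2 = 1.0 - rss / tss if tss > 0 else np.nan
            rows.append(
                {
                    "subset": subset,
                    "n_predictors": p,
                    "k": k,
                    "loglik": llf,
                    "aic": aic,
                    "aicc": aicc,
                    "adj_r2": adjusted_r2(r2, n, p),
                    "condition_number": float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf,
                    "coefficients": dict(zip(("intercept",) + subset, beta)),
                }
            )
    table = pd.DataFrame(rows)
    table["criterion_value"] = table[criterion]
    table = table.sort_values(
        ["criterion_value", "n_predictors", "subset"]
    ).reset_index(drop=True)
    table["delta"] = table["criterion_value"] - table["criterion_value"].iloc[0]
    rel = np.exp(-0.5 * table["delta"].to_numpy())
    table["weight"] = rel / rel.sum()
    return ModelSelectionResult(table=table, criterion=criterion, n_obs=n)


# ----------------------------------------------------------------------
# diagnostics


def residual_diagnostics(
    residuals: np.ndarray,
    exog: np.ndarray | None = None,
    response: np.ndarray | None = None,
) -> dict:
    """Normality and homoscedasticity checks on a fitted model's residuals.

    Returns the Kolmogorov-Smirnov statistic and p-value on standardized
    residuals (Lilliefors correction for the estimated mean and variance),
    a Shapiro-Wilk test on the raw response if supplied (the pre-modelling
    normality screen), and a Breusch-Pagan heteroscedasticity test if the
    model matrix ``exog`` is supplied.
    """
    r = np.asarray(residuals, dtype=float)
    if len(r) < 3:
        raise ValueError("need at least 3 residuals")
    sd = r.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate residuals: zero variance")
    z = (r - r.mean()) / sd
    ks_stat, ks_p = lilliefors(z, dist="norm")
    out = {"ks_stat": float(ks_stat), "ks_p": float(ks_p), "n": int(len(r))}
    if response is not None:
        sw_stat, sw_p = stats.shapiro(np.asarray(response, dtype=float))
        out["shapiro_stat"] = float(sw_stat)
        out["shapiro_p"] = float(sw_p)
    if exog is not None:
        x = np.asarray(exog, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        if not np.allclose(x[:, 0], 1.0):
            x = np.column_stack([np.ones(len(x)), x])
        bp_stat, bp_p, _, _ = het_breuschpagan(r, x)
        out["bp_stat"] = float(bp_stat)
        out["bp_p"] = float(bp_p)
    return out
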