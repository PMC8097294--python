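"""Multiple regression of dimorphism on genetic-architecture predictors.

Which parts of the exploratory line-mean genetic matrix are correlated
with the current level of sexual dimorphism?  The response is the
transformed dimorphism log10(|D| + 0.01) and the candidate predictors are
the per-gene summaries: mean expression E_bar, tissue specificity tau,
log10(g_bar), r_MF, log10(|m - f|), the aggregate cross-gene correlations
r_w_bar and r_b_bar, |r_dw| and log10(|r_db| + 0.01), plus any user 0/1
indicator columns.  Antagonistic selection predicts a positive g_bar and
negative r_MF relationship; concordant selection predicts positive
relationships with the variance and correlation asymmetries.

Because the expression of different genes is measured on the same lines,
ordinary standard errors are invalid; inference instead bootstraps at the
level of inbred lines, recomputing line means, every derived predictor
and the response in each resample, and declares an effect significant
when its 2.5% and 97.5% bootstrap quantiles share a sign.  "Variance
explained" per predictor is the squared semipartial correlation (the
increment in model R^2 when the predictor is added last), times 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genewise import (
    LineMeanTable,
    aggregate_correlations,
    dimorphism_and_class,
    per_gene_genetics,
    transform_dimorphism,
)

__all__ = [
    "DEFAULT_PREDICTORS",
    "RegressionSpec",
    "DimorphismRegression",
    "DimorphismRegressionResults",
    "add_indicator_covariates",
    "build_design",
]

DEFAULT_PREDICTORS = (
    "E_bar",
    "tau",
    "log10_gbar",
    "r_mf",
    "log10_abs_m_minus_f",
    "rw_bar",
    "rb_bar",
    "abs_rdw",
    "log10_abs_rdb",
)

#: offset guarding the log transforms of |r_db| and |D| against zeros
LOG_OFFSET = 0.01


@dataclass(frozen=True)
class RegressionSpec:
    """Predictor list and gene subset for one regression."""

    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    subset: str = "all"  # all | biased (|D|>1) | unbiased (|D|<=1)

    def __post_init__(self) -> None:
        if self.subset not in ("all", "biased", "unbiased"):
            raise ValueError(f"unknown subset {self.subset!r}")


def _derived_columns(summary: pd.DataFrame) -> pd.DataFrame:
    out = summary.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        out["log10_gbar"] = np.log10(out["g_bar"].where(out["g_bar"] > 0))
        out["log10_abs_m_minus_f"] = np.log10(
            np.abs(out["m"] - out["f"]).where(np.abs(out["m"] - out["f"]) > 0)
        )
        out["log10_abs_rdb"] = np.log10(out["abs_rdb"] + LOG_OFFSET)
    return out


def build_design(
    summary: pd.DataFrame, spec: RegressionSpec
) -> tuple[pd.Series, pd.DataFrame]:
    """Response and predictor matrix (complete cases) for one summary table."""
    df = _derived_columns(summary)
    if spec.subset == "biased":
        df = df[np.abs(df["D"]) > 1]
    elif spec.subset == "unbiased":
        df = df[np.abs(df["D"]) <= 1]
    missing = [p for p in spec.predictors if p not in df.columns]
    if missing:
        raise KeyError(f"predictors absent from summary table: {missing}")
    y = transform_dimorphism(df["D"])
    X = df[list(spec.predictors)]
    keep = np.isfinite(y) & np.isfinite(X).all(axis=1)
    return y[keep], X[keep]


def _drop_aliased(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Greedily drop constant or linearly dependent columns (later ones lose)."""
    dropped = []
    kept: list[str] = []
    arr = np.column_stack([np.ones(len(X))])
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        trial = np.column_stack([arr, v])
        if np.linalg.matrix_rank(trial) > arr.shape[1]:
            arr = trial
            kept.append(col)
        else:
            dropped.append(col)
    return X[kept], dropped


def add_indicator_covariates(
    summary: pd.DataFrame, gene_sets: dict[str, list[str]]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Add 0/1 membership columns (e.g. fitness-effect gene lists).

    Returns the augmented table and, per set, the number of listed ids
    absent from the summary (reported, not fatal).
    """
    out = summary.copy()
    missing_counts = {}
    for name, ids in gene_sets.items():
        ids = set(ids)
        out[name] = [1.0 if g in ids else 0.0 for g in out.index]
        missing_counts[name] = len(ids - set(out.index))
    return out, missing_counts


def _fit_ols(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(np.column_stack([np.ones(len(X)), X]), y, rcond=None)
    return coef


@dataclass
class DimorphismRegressionResults:
    """Point fit plus line-level bootstrap distribution.

    ``params`` are the point-estimate OLS slopes; ``table`` carries the
    bootstrap median, 2.5%/97.5% quantiles, the sign-consistency
    significance flag and the partial R^2 (in percent) per predictor.
    """

    spec: RegressionSpec
    params: pd.Series
    model_r2: float
    partial_r2: pd.Series
    table: pd.DataFrame
    n_obs: int
    n_boot: int
    seed: int | None
    dropped: list[str] = field(default_factory=list)
    n_failed_boot: pd.Series | None = None
    ols_results: object | None = None

    def summary(self) -> str:
        head = (
            f"Dimorphism regression (subset={self.spec.subset}, n={self.n_obs} genes, "
            f"{self.n_boot} line-level bootstrap resamples"
            + (f", seed={self.seed}" if self.seed is not None else "")
            + ")\n"
            f"model R^2 = {self.model_r2:.3f}; partial R^2 = squared semipartial x 100\n"
        )
        if self.dropped:
            head += f"dropped aliased predictors: {', '.join(self.dropped)}\n"
        with pd.option_context("display.width", 120, "display.precision", 4):
            return head + self.table.to_string()


class DimorphismRegression:
    """OLS of transformed dimorphism on G-derived predictors, bootstrapped
    over inbred lines.

    Parameters
    ----------
    summary
        Per-gene summary table (one row per retained gene).
    line_means
        The retained genes' line-mean table; required for the line-level
        bootstrap, in which line means, D, the genetic parameters and the
        aggregate correlations are all recomputed per resample.
    spec
        Predictor list and gene subset.
    """

    def __init__(
        self,
        summary: pd.DataFrame,
        line_means: LineMeanTable | None = None,
        spec: RegressionSpec = RegressionSpec(),
    ):
        self.summary = summary
        self.line_means = line_means
        self.spec = spec
        y, X = build_design(summary, spec)
        if len(y) < len(spec.predictors) + 2:
            raise ValueError(
                f"only {len(y)} complete cases for {len(spec.predictors)} predictors"
            )
        X, self._dropped = _drop_aliased(X)
        self._y, self._X = y, X

    # -- point fit -----------------------------------------------------
    def fit_once(self) -> tuple[pd.Series, float, pd.Series, object]:
        """OLS slopes, model R^2 and add-last partial R^2 per predictor."""
        X = sm.add_constant(self._X.to_numpy(dtype=float))
        res = sm.OLS(self._y.to_numpy(dtype=float), X).fit()
        names = list(self._X.columns)
        params = pd.Series(res.params[1:], index=names, name="slope")
        r2 = float(res.rsquared)
        partial = {}
        for j, name in enumerate(names):
            sub = np.delete(X, j + 1, axis=1)
            r2_without = sm.OLS(self._y.to_numpy(dtype=float), sub).fit().rsquared
            partial[name] = 100.0 * (r2 - float(r2_without))
        return params, r2, pd.Series(partial, name="partial_r2"), res

    # -- bootstrap -----------------------------------------------------
    def _recomputed_summary(self, lm: LineMeanTable) -> pd.DataFrame:
        base = self.summary.loc[lm.gene_ids]
        dim = dimorphism_and_class(lm)
        gen = per_gene_genetics(lm)
        agg = aggregate_correlations(lm)
        out = pd.concat(
            [
                dim,
                gen,
                agg,
                base[[c for c in base.columns if c in ("E_bar", "tau")]],
            ],
            axis=1,
        )
        # indicator / user columns pass through unchanged
        extra = [
            c
            for c in self.spec.predictors
            if c not in out.columns and c in base.columns
        ]
        for c in extra:
            out[c] = base[c]
        # E_bar is recomputed as the grand mean of the resampled line means
        out["E_bar"] = np.nanmean(lm.values, axis=(1, 2))
        return out

    def fit(self, n_boot: int = 1000, seed: int | None = 0) -> DimorphismRegressionResults:
        """Point fit plus ``n_boot`` line-level bootstrap refits."""
        params, r2, partial, ols_res = self.fit_once()
        names = list(self._X.columns)
        if n_boot <= 0 or self.line_means is None:
            if n_boot > 0:
                raise ValueError("line_means required for the line-level bootstrap")
            table = pd.DataFrame(
                {"slope": params, "partial_r2": partial}
            )
            return DimorphismRegressionResults(
                self.spec, params, r2, partial, table, len(self._y), 0, seed,
                self._dropped, None, ols_res,
            )
        rng = np.random.default_rng(seed)
        L = len(self.line_means.lines)
        if L < 5:
            raise ValueError("line-level bootstrap needs >=5 lines")
        slopes = np.full((n_boot, len(names)), np.nan)
        for it in range(n_boot):
            idx = rng.integers(0, L, L)
            lm_b = self.line_means.resample_lines(idx)
            summ_b = self._recomputed_summary(lm_b)
            try:
                y, X = build_design(summ_b, RegressionSpec(tuple(names), self.spec.subset))
            except KeyError:
                continue
            if len(y) < len(names) + 2:
                continue
            Xv = X.to_numpy(dtype=float)
            ok = Xv.std(axis=0) > 0
            if not ok.all():
                coef = np.full(len(names), np.nan)
                coef_sub = _fit_ols(y.to_numpy(dtype=float), Xv[:, ok])[1:]
                coef[ok] = coef_sub
                slopes[it] = coef
            else:
                slopes[it] = _fit_ols(y.to_numpy(dtype=float), Xv)[1:]
        med, lo, hi = np.nanquantile(slopes, [0.5, 0.025, 0.975], axis=0)
        n_failed = pd.Series(
            np.isnan(slopes).sum(axis=0), index=names, name="n_missing_boot"
        )
        table = pd.DataFrame(
            {
                "slope": params,
                "median": med,
                "q2.5": lo,
                "q97.5": hi,
                "significant": np.sign(lo) == np.sign(hi),
                "partial_r2": partial,
                "n_missing_boot": n_failed,
            },
            index=names,
        )
        table.loc[~np.isfinite(table["q2.5"]) | ~np.isfinite(table["q97.5"]),
                  "significant"] = False
        return DimorphismRegressionResults(
            self.spec, params, r2, partial, table, len(self._y), n_boot, seed,
            self._dropped, n_failed, ols_res,
        )
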