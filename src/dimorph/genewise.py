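"""Per-gene genetic summaries from an inbred-line expression panel.

The pipeline mirrors the classic inbred-panel design: each line is assayed
in both sexes with replicate chips, expression on the log2 scale.  Per
gene it

1. screens for genetic variation with a restricted-likelihood ratio test
   of the mixed model (fixed: sex [, probe, probe x sex]; random: line,
   line x sex [, line x probe]) against the model with all random terms
   removed (chi-square with 2 df, or 3 df for multi-probe genes);
2. computes least-squares line means per sex (for the balanced
   single-probe design these are plain replicate means);
3. derives dimorphism D (male minus female mean, a log2 ratio), the bias
   class (male-biased D > 1, female-biased D < -1, unbiased |D| <= 1),
   the sex-specific between-line variances m and f, their cross-sex
   covariance b, the intersexual correlation r_MF = b / sqrt(m f), the
   average variance g_bar and the variance-asymmetry statistic d;
4. aggregates each gene's correlations with every other gene's line means
   within and between sexes (r_w_bar, r_b_bar and the asymmetry versions
   |r_dw|, |r_db|), the quantities that govern indirect responses of
   dimorphism to selection on other transcripts.

Between-line (co)variances are reported on the inbred-line scale, exactly
as the sample covariance matrix of sex-specific line means (no outbred
conversion factor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ExpressionDataset",
    "LineMeanTable",
    "screen_gene",
    "screen_genes",
    "line_means",
    "dimorphism_and_class",
    "per_gene_genetics",
    "aggregate_correlations",
    "expression_covariates",
    "tissue_specificity",
    "transform_dimorphism",
    "gene_summaries",
]

SEXES = ("M", "F")
_TINY = 1e-12


@dataclass
class ExpressionDataset:
    """Genes x samples log2 expression with (line, sex, replicate) labels.

    ``samples`` is a DataFrame with columns ``line``, ``sex`` ("M"/"F"),
    ``rep`` and ``probe`` (empty string when single-probe), one row per
    column of ``values``.  Missing cells are NaN, never silent zeros.
    """

    gene_ids: list[str]
    samples: pd.DataFrame
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.samples = self.samples.reset_index(drop=True)
        if "probe" not in self.samples.columns:
            self.samples = self.samples.assign(probe="")
        if len(self.gene_ids) != len(set(self.gene_ids)):
            raise ValueError("gene ids must be unique")
        if self.values.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples"
            )
        bad_sex = set(self.samples["sex"]) - set(SEXES)
        if bad_sex:
            raise ValueError(f"unknown sex labels {bad_sex}")

    @property
    def lines(self) -> list:
        return sorted(self.samples["line"].unique())

    @property
    def n_lines(self) -> int:
        return self.samples["line"].nunique()

    # -- I/O -----------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        cols = []
        for _, s in self.samples.iterrows():
            col = f"{s['line']}:{s['sex']}:{s['rep']}"
            if s["probe"]:
                col += f":{s['probe']}"
            cols.append(col)
        df = pd.DataFrame(self.values, index=self.gene_ids, columns=cols)
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t", float_format="%.12g", na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionDataset":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                 float_precision="round_trip")
        recs = []
        for j, col in enumerate(df.columns):
            parts = col.split(":")
            if len(parts) not in (3, 4):
                raise ValueError(
                    f"{path}: column {j + 1} ({col!r}) is not line:sex:rep[:probe]"
                )
            line, sex, rep = parts[0], parts[1], parts[2]
            probe = parts[3] if len(parts) == 4 else ""
            recs.append({"line": line, "sex": sex, "rep": rep, "probe": probe})
        return cls(list(df.index.astype(str)), pd.DataFrame(recs), df.values)


@dataclass
class LineMeanTable:
    """Least-squares means per (gene, line, sex).

    ``values`` has shape (genes, lines, 2) with the last axis ordered
    (M, F); missing cells are NaN.
    """

    gene_ids: list[str]
    lines: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.lines), 2):
            raise ValueError("line-mean table dimensions inconsistent")

    def male(self) -> np.ndarray:
        return self.values[:, :, 0]

    def female(self) -> np.ndarray:
        return self.values[:, :, 1]

    def complete_genes(self) -> np.ndarray:
        """Boolean mask of genes with all (line, sex) means present."""
        return np.isfinite(self.values).all(axis=(1, 2))

    def subset_genes(self, mask: np.ndarray) -> "LineMeanTable":
        idx = np.flatnonzero(np.asarray(mask))
        return LineMeanTable(
            [self.gene_ids[i] for i in idx], self.lines, self.values[idx]
        )

    def resample_lines(self, line_idx: np.ndarray) -> "LineMeanTable":
        """Bootstrap view: lines taken (with repetition) from ``line_idx``."""
        return LineMeanTable(
            self.gene_ids,
            [self.lines[i] for i in line_idx],
            self.values[:, line_idx, :],
        )

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{line}:{sex}" for sex in SEXES for line in self.lines]
        flat = np.concatenate([self.male(), self.female()], axis=1)
        df = pd.DataFrame(flat, index=self.gene_ids, columns=cols)
        df.index.name = "gene_id"
        return df


# ======================================================================
# mixed-model screen
# ======================================================================


def _balanced_single_probe(samples: pd.DataFrame) -> bool:
    if samples["probe"].nunique() > 1:
        return False
    counts = samples.groupby(["line", "sex"], sort=False).size()
    lines = samples["line"].nunique()
    if len(counts) != 2 * lines:
        return False
    return counts.nunique() == 1 and counts.iloc[0] >= 2


def _balanced_suffstats(y: np.ndarray, samples: pd.DataFrame):
    """Sufficient statistics of the balanced single-probe design.

    Returns (SSw, dfw, SSu, SSv, L, R): within-cell sum of squares and its
    df, and the between-line sums of squares of the scaled sex-sum and
    sex-difference contrasts of the cell means, each with L-1 df.
    """
    cells = pd.DataFrame({"line": samples["line"], "sex": samples["sex"], "y": y})
    means = cells.groupby(["line", "sex"], sort=True)["y"].mean().unstack("sex")
    counts = cells.groupby(["line", "sex"], sort=True).size()
    L = means.shape[0]
    R = int(counts.iloc[0])
    fitted = means.stack().rename("cell")
    merged = cells.join(fitted, on=["line", "sex"])
    ssw = float(((merged["y"] - merged["cell"]) ** 2).sum())
    dfw = 2 * L * (R - 1)
    u = (means["M"].values + means["F"].values) / math.sqrt(2)
    v = (means["M"].values - means["F"].values) / math.sqrt(2)
    ssu = float(((u - u.mean()) ** 2).sum())
    ssv = float(((v - v.mean()) ** 2).sum())
    return ssw, dfw, ssu, ssv, L, R


def _balanced_negll(theta, ssw, dfw, ssu, ssv, L, R):
    """-2x restricted loglik (up to constant) from the contrast decomposition.

    Contrast variances: within-cell residuals ~ sigma_e^2; the L-1 sex-sum
    contrasts ~ 2 sigma_a^2 + sigma_c^2 + sigma_e^2/R; the L-1
    sex-difference contrasts ~ sigma_c^2 + sigma_e^2/R, where sigma_a^2 is
    the line variance and sigma_c^2 the line x sex variance.
    """
    sa, sc, se = theta
    lu = 2.0 * sa + sc + se / R
    lv = sc + se / R
    if se <= 0 or lu <= 0 or lv <= 0:
        return np.inf
    out = (L - 1) * (math.log(lu) + math.log(lv)) + ssu / lu + ssv / lv
    if dfw > 0:
        out += dfw * math.log(se) + ssw / se
    return 0.5 * out


def _balanced_reml_full(ssw, dfw, ssu, ssv, L, R) -> float:
    """Maximized restricted loglik of the full random-effects model."""
    se0 = ssw / dfw if dfw > 0 else _TINY
    lu0 = ssu / (L - 1)
    lv0 = ssv / (L - 1)
    sc0 = lv0 - se0 / R
    sa0 = (lu0 - lv0) / 2.0
    if se0 > 0 and sc0 >= 0 and sa0 >= 0:
        # interior solution: each contrast class gets its own MLE
        return -_balanced_negll((sa0, sc0, se0), ssw, dfw, ssu, ssv, L, R)
    x0 = np.array([max(sa0, 0.0), max(sc0, 0.0), max(se0, _TINY)])
    scale = max(se0, lu0, lv0, _TINY)
    res = optimize.minimize(
        _balanced_negll,
        x0,
        args=(ssw, dfw, ssu, ssv, L, R),
        method="L-BFGS-B",
        bounds=[(0.0, None), (0.0, None), (scale * 1e-10, None)],
    )
    return -float(res.fun)


def _balanced_reml_null(ssw, dfw, ssu, ssv, L, R) -> float:
    se = (ssw + R * (ssu + ssv)) / (dfw + 2 * (L - 1))
    return -_balanced_negll((0.0, 0.0, se), ssw, dfw, ssu, ssv, L, R)


def _fixed_design(samples: pd.DataFrame) -> np.ndarray:
    """Fixed-effect design: intercept + sex (+ probe + probe x sex)."""
    sex = (samples["sex"] == "M").astype(float).values
    cols = [np.ones(len(samples)), sex]
    probes = sorted(samples["probe"].unique())
    if len(probes) > 1:
        for p in probes[1:]:
            ind = (samples["probe"] == p).astype(float).values
            cols.append(ind)
            cols.append(ind * sex)
    return np.column_stack(cols)


def _generic_reml(y, X, samples: pd.DataFrame, theta) -> float:
    """Restricted loglik with per-line covariance blocks.

    theta = (sigma_line, sigma_line_sex, sigma_line_probe, sigma_e), all
    variances.  Works for any per-line layout; used for multi-probe or
    unbalanced designs.
    """
    s_l, s_ls, s_lp, s_e = theta
    if s_e <= 0 or min(s_l, s_ls, s_lp) < 0:
        return -np.inf
    p = X.shape[1]
    logdet_v = 0.0
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    probes = sorted(samples["probe"].unique())
    for _, idx in samples.groupby("line", sort=False).indices.items():
        yi = y[idx]
        xi = X[idx]
        n_i = len(idx)
        v = s_e * np.eye(n_i) + s_l * np.ones((n_i, n_i))
        sx = samples["sex"].values[idx]
        for s in SEXES:
            z = (sx == s).astype(float)
            v += s_ls * np.outer(z, z)
        if len(probes) > 1:
            pr = samples["probe"].values[idx]
            for pb in probes:
                z = (pr == pb).astype(float)
                v += s_lp * np.outer(z, z)
        sign, ld = np.linalg.slogdet(v)
        if sign <= 0:
            return -np.inf
        logdet_v += ld
        vinv_y = np.linalg.solve(v, yi)
        vinv_x = np.linalg.solve(v, xi)
        xtvx += xi.T @ vinv_x
        xtvy += xi.T @ vinv_y
        ytvy += yi @ vinv_y
    sign, ld_x = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(xtvx, xtvy)
    quad = ytvy - beta @ xtvy
    return -0.5 * (logdet_v + ld_x + quad)


def _generic_screen(y, samples: pd.DataFrame) -> tuple[float, int]:
    X = _fixed_design(samples)
    multi = samples["probe"].nunique() > 1
    df_used = 3 if multi else 2
    # null: iid residuals only
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(((y - X @ beta) ** 2).sum())
    n, p = X.shape
    se_null = max(rss / max(n - p, 1), _TINY)
    ll_null = _generic_reml(y, X, samples, (0.0, 0.0, 0.0, se_null))

    var0 = max(np.var(y), _TINY)

    def negll(log_theta):
        theta = np.exp(log_theta)
        if not multi:
            theta = np.array([theta[0], theta[1], 0.0, theta[2]])
        return -_generic_reml(y, X, samples, theta)

    k = 4 if multi else 3
    x0 = np.log(np.full(k, var0 / k))
    res = optimize.minimize(negll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    ll_full = -float(res.fun)
    lrt = max(0.0, 2.0 * (ll_full - ll_null))
    return float(stats.chi2.sf(lrt, df_used)), df_used


def screen_gene(y: np.ndarray, samples: pd.DataFrame) -> tuple[float, int]:
    """LRT p-value for total line effects in one gene, and the df used.

    Compares the restricted likelihood of the full mixed model with that
    of the model with every random term removed; the statistic is referred
    to a plain chi-square (2 df single-probe, 3 df multi-probe), which is
    conservative at the variance boundary.
    """
    ok = np.isfinite(y)
    y = y[ok]
    samples = samples.loc[ok].reset_index(drop=True)
    if samples["line"].nunique() < 2 or samples["sex"].nunique() < 2:
        raise ValueError("gene unscreenable: need >=2 lines and both sexes")
    if _balanced_single_probe(samples):
        ss = _balanced_suffstats(y, samples)
        ll_full = _balanced_reml_full(*ss)
        ll_null = _balanced_reml_null(*ss)
        lrt = max(0.0, 2.0 * (ll_full - ll_null))
        return float(stats.chi2.sf(lrt, 2)), 2
    return _generic_screen(y, samples)


def screen_genes(dataset: ExpressionDataset, alpha: float = 0.01) -> pd.DataFrame:
    """Screen every gene; returns lrt_p, df_used and the retention flag."""
    rows = []
    balanced = _balanced_single_probe(dataset.samples)
    if balanced:
        stats_cache = _vectorized_balanced_stats(dataset)
    for i, gid in enumerate(dataset.gene_ids):
        y = dataset.values[i]
        if balanced and np.isfinite(y).all():
            ss = stats_cache[i]
            ll_full = _balanced_reml_full(*ss)
            ll_null = _balanced_reml_null(*ss)
            lrt = max(0.0, 2.0 * (ll_full - ll_null))
            p, df_used = float(stats.chi2.sf(lrt, 2)), 2
        else:
            try:
                p, df_used = screen_gene(y, dataset.samples)
            except ValueError:
                rows.append({"gene_id": gid, "lrt_p": np.nan, "df_used": 0,
                             "retained": False})
                continue
        rows.append({"gene_id": gid, "lrt_p": p, "df_used": df_used,
                     "retained": p < alpha})
    return pd.DataFrame(rows).set_index("gene_id")


def _vectorized_balanced_stats(dataset: ExpressionDataset):
    """Per-gene (SSw, dfw, SSu, SSv, L, R) computed in one pass."""
    samples = dataset.samples
    lines = sorted(samples["line"].unique())
    line_code = samples["line"].map({l: i for i, l in enumerate(lines)}).values
    sex_code = (samples["sex"] == "F").astype(int).values
    L = len(lines)
    cell = line_code * 2 + sex_code
    counts = np.bincount(cell, minlength=2 * L).astype(float)
    R = int(counts[0])
    vals = dataset.values
    G = vals.shape[0]
    sums = np.zeros((G, 2 * L))
    np.add.at(sums.T, cell, vals.T)
    means = sums / counts  # (G, 2L); cell order line-major, M then F
    ssw = ((vals - means[:, cell]) ** 2).sum(axis=1)
    dfw = 2 * L * (R - 1)
    mm = means[:, 0::2]
    mf = means[:, 1::2]
    u = (mm + mf) / math.sqrt(2)
    v = (mm - mf) / math.sqrt(2)
    ssu = ((u - u.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ssv = ((v - v.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    return [(float(ssw[i]), dfw, float(ssu[i]), float(ssv[i]), L, R) for i in range(G)]


# ======================================================================
# line means and derived statistics
# ======================================================================


def _ls_means_multiprobe(y: np.ndarray, samples: pd.DataFrame,
                         lines: list) -> np.ndarray:
    """Probe-adjusted least-squares means for one multi-probe gene.

    Cells (line, sex) get their own indicator; probe main effects and
    probe x sex interactions are sum-coded so each coefficient set
    averages to zero over probes, making the cell coefficient the LS mean.
    """
    ok = np.isfinite(y)
    y = y[ok]
    sub = samples.loc[ok]
    probes = sorted(sub["probe"].unique())
    cell_cols = []
    keys = [(line, sex) for line in lines for sex in SEXES]
    for line, sex in keys:
        cell_cols.append(((sub["line"] == line) & (sub["sex"] == sex)).astype(float).values)
    X = [np.column_stack(cell_cols)]
    if len(probes) > 1:
        sex_sign = np.where(sub["sex"] == "M", 1.0, -1.0)
        for p in probes[:-1]:
            contrast = (sub["probe"] == p).astype(float).values - (
                sub["probe"] == probes[-1]
            ).astype(float).values
            X.append(contrast[:, None])
            X.append((contrast * sex_sign)[:, None])
    X = np.hstack(X)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    out = np.full((len(lines), 2), np.nan)
    present = X[:, : len(keys)].sum(axis=0) > 0
    for k, (line, sex) in enumerate(keys):
        if present[k]:
            out[lines.index(line), SEXES.index(sex)] = coef[k]
    return out


def line_means(dataset: ExpressionDataset) -> LineMeanTable:
    """Least-squares means per (gene, line, sex).

    Balanced single-probe data reduce to plain replicate means; for
    multi-probe genes probe effects are adjusted out with equal probe
    weights.  Missing (line, sex) cells stay NaN.
    """
    lines = dataset.lines
    L = len(lines)
    G = len(dataset.gene_ids)
    out = np.full((G, L, 2), np.nan)
    single = dataset.samples["probe"].nunique() <= 1
    if single:
        line_code = dataset.samples["line"].map(
            {l: i for i, l in enumerate(lines)}
        ).values
        sex_code = dataset.samples["sex"].map({"M": 0, "F": 1}).values
        cell = line_code * 2 + sex_code
        vals = dataset.values
        finite = np.isfinite(vals)
        sums = np.zeros((G, 2 * L))
        cnts = np.zeros((G, 2 * L))
        np.add.at(sums.T, cell, np.where(finite, vals, 0.0).T)
        np.add.at(cnts.T, cell, finite.T.astype(float))
        with np.errstate(invalid="ignore"):
            means = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
        out = means.reshape(G, L, 2)
    else:
        for i in range(G):
            out[i] = _ls_means_multiprobe(dataset.values[i], dataset.samples, lines)
    return LineMeanTable(list(dataset.gene_ids), lines, out)


def dimorphism_and_class(lm: LineMeanTable, cutoff: float = 1.0) -> pd.DataFrame:
    """Dimorphism D (mean male-minus-female line mean) and its bias class.

    Classes: MB if D > cutoff, FB if D < -cutoff, UB if |D| <= cutoff
    (closed boundary); the default cutoff of 1 log2 unit is a twofold
    expression ratio.
    """
    if cutoff <= 0:
        raise ValueError("bias cutoff must be positive")
    diff = lm.male() - lm.female()
    D = np.nanmean(diff, axis=1)
    cls = np.where(D > cutoff, "MB", np.where(D < -cutoff, "FB", "UB"))
    cls = np.where(np.isfinite(D), cls, "NA")
    return pd.DataFrame({"D": D, "bias_class": cls}, index=lm.gene_ids)


def per_gene_genetics(lm: LineMeanTable) -> pd.DataFrame:
    """Sample between-line (co)variances of the sex-specific line means.

    These are the entries of the exploratory genetic matrix built from
    line means: per gene the male and female variances m and f, their
    covariance b, r_MF = b / sqrt(m f), g_bar = (m + f)/2 and
    d = sqrt(m f) / g_bar (inbred-line scale, no correction factor).
    """
    if len(lm.lines) < 3:
        raise ValueError("need >=3 lines for between-line (co)variances")
    male, female = lm.male(), lm.female()
    mask = np.isfinite(male) & np.isfinite(female)
    n = mask.sum(axis=1).astype(float)
    mm = np.where(mask, male, 0.0)
    ff = np.where(mask, female, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu_m = mm.sum(axis=1) / n
        mu_f = ff.sum(axis=1) / n
        dm = np.where(mask, male - mu_m[:, None], 0.0)
        df_ = np.where(mask, female - mu_f[:, None], 0.0)
        m = (dm**2).sum(axis=1) / (n - 1)
        f = (df_**2).sum(axis=1) / (n - 1)
        b = (dm * df_).sum(axis=1) / (n - 1)
        mf = m * f
        r_mf = np.where(mf > 0, b / np.sqrt(np.where(mf > 0, mf, 1.0)), np.nan)
        g_bar = (m + f) / 2.0
        d = np.where(mf > 0, np.sqrt(np.where(mf > 0, mf, 1.0)) / g_bar, np.nan)
    bad = n < 3
    for arr in (m, f, b, r_mf, g_bar, d):
        arr[bad] = np.nan
    return pd.DataFrame(
        {"m": m, "f": f, "b": b, "r_mf": r_mf, "g_bar": g_bar, "d": d},
        index=lm.gene_ids,
    )


def aggregate_correlations(lm: LineMeanTable) -> pd.DataFrame:
    """Average correlations of each gene with all other genes' line means.

    For gene i over the n genes with nonzero variance in both sexes:

    * ``rw_bar``  = (sum_{j!=i} r_MiMj + r_FiFj) / (2(n-1))
    * ``rb_bar``  = (sum_{j!=i} r_MiFj + r_FiMj) / (2(n-1))
    * ``abs_rdw`` = |sum_{j!=i} r_MiMj - r_FiFj| / (2(n-1))
    * ``abs_rdb`` = |sum_{j!=i} r_MiFj - r_FiMj| / (2(n-1))

    computed in O(genes x lines) from standardized line-mean matrices;
    genes with zero variance in either sex are excluded from the sums
    (with n adjusted) and get NaN statistics themselves.
    """
    male, female = lm.male(), lm.female()
    complete = np.isfinite(male).all(axis=1) & np.isfinite(female).all(axis=1)
    with np.errstate(invalid="ignore"):
        sd_m = np.nanstd(male, axis=1, ddof=1)
        sd_f = np.nanstd(female, axis=1, ddof=1)
    valid = complete & (sd_m > 0) & (sd_f > 0)
    out = pd.DataFrame(
        np.nan,
        index=lm.gene_ids,
        columns=["rw_bar", "rb_bar", "abs_rdw", "abs_rdb"],
    )
    n = int(valid.sum())
    if n < 2:
        return out
    L = len(lm.lines)

    def standardize(x):
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=1, keepdims=True)
        return (x - mu) / sd

    zm = standardize(male[valid])  # (n, L)
    zf = standardize(female[valid])
    denom = float(L - 1)
    sm = zm.sum(axis=0)  # (L,)
    sf = zf.sum(axis=0)
    # row sums of the n x n correlation matrices, diagonal included
    row_mm = zm @ sm / denom
    row_ff = zf @ sf / denom
    row_mf = zm @ sf / denom  # sum_j corr(Mi, Fj)
    row_fm = zf @ sm / denom  # sum_j corr(Fi, Mj)
    diag_b = (zm * zf).sum(axis=1) / denom  # corr(Mi, Fi)
    k = 2.0 * (n - 1)
    rw = (row_mm - 1.0 + row_ff - 1.0) / k
    rb = (row_mf - diag_b + row_fm - diag_b) / k
    rdw = np.abs((row_mm - row_ff) / k)  # diagonals (1 each) cancel
    rdb = np.abs((row_mf - row_fm) / k)  # diagonal corr(Mi,Fi) cancels
    out.loc[np.array(lm.gene_ids)[valid], :] = np.column_stack([rw, rb, rdw, rdb])
    return out


# ======================================================================
# expression level and tissue specificity
# ======================================================================


def tissue_specificity(
    tissue_table: pd.DataFrame, gene_map: Mapping[str, str] | None = None
) -> pd.Series:
    """Tissue-specificity index tau in [0, 1] per gene.

    tau = sum_t (1 - x_t / max_t x_t) / (n_tissues - 1) over the rows
    (tissues) of ``tissue_table``; 0 for uniform expression, 1 for
    single-tissue expression.  Requires nonnegative intensities: if any
    value is negative (log-scale input), the whole table is shifted up by
    the dataset minimum.  With ``gene_map`` (transcript -> gene), taus of
    a gene's transcripts are averaged.
    """
    if tissue_table.shape[0] < 2:
        raise ValueError("tau needs >=2 tissues")
    x = tissue_table.to_numpy(dtype=float)
    lo = np.nanmin(x)
    if lo < 0:
        x = x - lo
    tmax = np.nanmax(x, axis=0)
    nt = x.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        xhat = np.where(tmax > 0, x / np.where(tmax > 0, tmax, 1.0), np.nan)
        tau = np.nansum(1.0 - xhat, axis=0) / (nt - 1)
    tau = np.where(tmax > 0, tau, np.nan)
    s = pd.Series(tau, index=tissue_table.columns, name="tau")
    if gene_map is not None:
        s = s.groupby(pd.Series(dict(gene_map)).reindex(s.index)).mean()
        s.name = "tau"
    return s


def expression_covariates(
    dataset: ExpressionDataset,
    tissue_table: pd.DataFrame | None = None,
    gene_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Mean expression E_bar (grand mean log2) and, if available, tau."""
    e_bar = np.nanmean(dataset.values, axis=1)
    out = pd.DataFrame({"E_bar": e_bar}, index=dataset.gene_ids)
    if tissue_table is not None:
        tau = tissue_specificity(tissue_table, gene_map)
        out["tau"] = tau.reindex(out.index)
    else:
        out["tau"] = np.nan
    return out


def transform_dimorphism(d):
    """log10(|D| + 0.01): tames the right tail without left-skewing near 0."""
    return np.log10(np.abs(d) + 0.01)


# ======================================================================
# one-call summary
# ======================================================================


def gene_summaries(
    dataset: ExpressionDataset,
    tissue_table: pd.DataFrame | None = None,
    gene_map: Mapping[str, str] | None = None,
    alpha: float = 0.01,
    screen: bool = True,
) -> tuple[pd.DataFrame, LineMeanTable]:
    """Run the whole per-gene pipeline.

    Returns the summary table (one row per gene; aggregate statistics are
    computed over retained genes only) and the line-mean table restricted
    to retained genes, the unit every downstream stage consumes.
    """
    if screen:
        scr = screen_genes(dataset, alpha=alpha)
    else:
        scr = pd.DataFrame(
            {"lrt_p": np.nan, "df_used": 0, "retained": True},
            index=pd.Index(dataset.gene_ids, name="gene_id"),
        )
    lm_all = line_means(dataset)
    retained = scr["retained"].reindex(dataset.gene_ids).fillna(False).to_numpy(bool)
    lm = lm_all.subset_genes(retained)
    summary = scr.copy()
    dim = dimorphism_and_class(lm_all)
    summary = summary.join(dim)
    summary = summary.join(per_gene_genetics(lm_all))
    agg = aggregate_correlations(lm)
    summary = summary.join(agg)
    summary = summary.join(expression_covariates(dataset, tissue_table, gene_map))
    summary["log10_D"] = transform_dimorphism(summary["D"])
    return summary, lm
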