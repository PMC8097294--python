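"""Estimating the sexed-trait G matrix from replicated line scores.

The design is the balanced inbred-panel one: each line carries replicate
trait-score vectors per sex, lines are assumed unrelated, and the
between-line covariance of line means estimates the genetic covariance
plus 1/R of the within-line (measurement) covariance.  The estimator is

    G_hat = S_B - S_W / R

with S_B the sample covariance of line means (L-1 df) and S_W the pooled
within-line covariance of replicates (L(R-1) df), followed by projection
onto the PSD cone and truncation to an effective rank selected by AICc on
a Gaussian rank-r factor model of the line means.  Uncertainty is
propagated by parametric resampling: the between- and within-line scatter
matrices are redrawn from central Wishart distributions at the estimated
parameters and degrees of freedom and the estimator re-applied to each
draw, giving replicate G matrices whose medians and 2.5%/97.5% quantiles
summarize any derived statistic.  This moment-plus-Wishart scheme is a
deliberately simple estimator of the same estimand a reduced-rank REML
fit would target; the method tag in the results records it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gmatrix import SexedG, SexedVariable
from .traits import TraitScoreTable, score_samples

__all__ = [
    "SexedGModel",
    "GEstimateResults",
    "GUncertaintySamples",
    "summarize_over_replicates",
]

METHOD_TAG = "manova_moment+psd_projection+aicc_rank"
SAMPLER_TAG = "balanced_wishart_parametric"


def _psd_project(a: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eigh((a + a.T) / 2)
    return (evecs * np.clip(evals, 0.0, None)) @ evecs.T


def _truncate_rank(a: np.ndarray, rank: int) -> np.ndarray:
    evals, evecs = np.linalg.eigh((a + a.T) / 2)
    order = np.argsort(evals)[::-1]
    keep = order[:rank]
    kept = np.clip(evals[keep], 0.0, None)
    return (evecs[:, keep] * kept) @ evecs[:, keep].T


class SexedGModel:
    """Genetic covariance model for replicated sexed trait scores.

    Parameters
    ----------
    rep_scores
        DataFrame indexed by (line, sex, rep) with one column per trait;
        NaN where a trait is not expressed in that sex.
    trait_sexes
        Mapping trait -> "M" | "F" | "both"; defines the sexed variable
        set (shared traits appear under both sexes).
    """

    def __init__(self, rep_scores: pd.DataFrame, trait_sexes: Mapping[str, str]):
        self.rep_scores = rep_scores
        self.trait_sexes = dict(trait_sexes)
        traits = list(rep_scores.columns)
        shared = [t for t in traits if self.trait_sexes.get(t) == "both"]
        male_only = [t for t in traits if self.trait_sexes.get(t) == "M"]
        female_only = [t for t in traits if self.trait_sexes.get(t) == "F"]
        self.variables: tuple[SexedVariable, ...] = tuple(
            [SexedVariable(t, "M") for t in shared + male_only]
            + [SexedVariable(t, "F") for t in shared + female_only]
        )
        self._design = self._build_design()

    @classmethod
    def from_traits(cls, table: TraitScoreTable, dataset) -> "SexedGModel":
        """Score the replicate-level expression data on a fitted trait set."""
        return cls(score_samples(table, dataset), table.trait_sexes)

    # -- data layout ---------------------------------------------------
    def _build_design(self) -> np.ndarray:
        """(L, R, d) array of sexed vectors, pairing same-labelled reps."""
        df = self.rep_scores
        lines = sorted(df.index.get_level_values("line").unique())
        reps = sorted(df.index.get_level_values("rep").unique())
        d = len(self.variables)
        out = np.full((len(lines), len(reps), d), np.nan)
        for li, line in enumerate(lines):
            for ri, rep in enumerate(reps):
                for vi, var in enumerate(self.variables):
                    key = (line, var.sex, rep)
                    if key in df.index:
                        out[li, ri, vi] = df.loc[key, var.trait]
        if not np.isfinite(out).all():
            raise ValueError(
                "incomplete design: every line needs the same replicate labels "
                "in both sexes"
            )
        self.lines = lines
        self.reps = reps
        return out

    # -- estimation ----------------------------------------------------
    def fit(self, rank: int | str = "aicc") -> "GEstimateResults":
        """Estimate G; ``rank`` is an integer or "aicc" for selection."""
        z = self._design  # (L, R, d)
        L, R, d = z.shape
        line_means = z.mean(axis=1)
        s_b = np.cov(line_means.T, ddof=1)
        s_b = np.atleast_2d(s_b)
        if R >= 2:
            dev = z - line_means[:, None, :]
            s_w = np.einsum("lrd,lre->de", dev, dev) / (L * (R - 1))
            g_raw = s_b - s_w / R
        else:
            warnings.warn(
                "no replication: error covariance unidentifiable, using raw "
                "line-mean covariance",
                RuntimeWarning,
                stacklevel=2,
            )
            s_w = np.zeros((d, d))
            g_raw = s_b
        g_psd = _psd_project(g_raw)
        if R >= 2 and np.trace(s_w) > 0:
            aicc_table, rank_fits = self._rank_selection(s_b, s_w / R, L, R, d)
        else:
            aicc_table, rank_fits = (
                pd.DataFrame(
                    [{"rank": d, "loglik": np.nan, "n_params": d * (d + 1) // 2,
                      "aicc": 0.0}]
                ).set_index("rank"),
                {d: g_psd},
            )
        if rank == "aicc":
            chosen = int(aicc_table["aicc"].idxmin())
        else:
            chosen = int(rank)
            if not 0 < chosen <= d:
                raise ValueError(f"rank must be in 1..{d}")
        g_hat = rank_fits[chosen] if chosen in rank_fits else _truncate_rank(
            g_psd, chosen
        )
        g = SexedG(self.variables, g_hat, validate=False)
        return GEstimateResults(
            model=self,
            g=g,
            g_raw=g_raw,
            rank=chosen,
            error_cov=s_w,
            n_lines=L,
            n_reps=R,
            aicc=aicc_table,
            method=METHOD_TAG,
        )

    @staticmethod
    def _rank_selection(s_b, err_mean, L, R, d):
        """AICc over rank-r Gaussian factor models of the line means.

        The between- and within-line scatters are modelled jointly:
        S_B ~ Wishart(G_r + Sigma_W / R) on n_b = L - 1 df and S_W ~
        Wishart(Sigma_W) on n_w = L (R - 1) df, with G_r PSD of rank <= r
        and Sigma_W free.  In the basis that diagonalizes S_B against
        S_W / R (generalized eigenvalues lambda_1 >= ... >= lambda_d) the
        profile restricted likelihood separates per coordinate: a freed
        genetic coordinate with lambda > 1 contributes
        -(n_b/2)(log lambda + 1) - n_w/2, a null one pools the two
        scatters into w_hat = (n_b lambda + n_w) / (n_b + n_w) and
        contributes -((n_b + n_w)/2)(log w_hat + 1).  Profiling the error
        covariance rather than plugging it in keeps chance fluctuations
        of the junk dimensions from masquerading as genetic rank.
        r d - r(r-1)/2 genetic parameters enter the penalty (the error
        part is common to all candidates); the small-sample correction
        uses the scalar degrees of freedom n = (L - 1) d.  Returns the
        criterion table and the per-rank genetic-matrix estimates.
        """
        n_b = L - 1
        n_w = L * (R - 1) if R >= 2 else 0
        n = n_b * d
        jitter = 1e-10 * max(np.trace(err_mean) / d, 1e-300)
        w = err_mean + np.eye(d) * jitter
        evw, evecw = np.linalg.eigh(w)
        evw = np.clip(evw, jitter, None)
        w_half = (evecw * np.sqrt(evw)) @ evecw.T
        w_inv_half = (evecw / np.sqrt(evw)) @ evecw.T
        s_tilde = w_inv_half @ s_b @ w_inv_half
        lam, u = np.linalg.eigh((s_tilde + s_tilde.T) / 2)
        order = np.argsort(lam)[::-1]
        lam, u = np.clip(lam[order], 1e-300, None), u[:, order]
        rows = []
        fits: dict[int, np.ndarray] = {}
        for r in range(1, d + 1):
            freed = np.zeros(d, dtype=bool)
            freed[:r] = lam[:r] > 1.0
            w_hat = (n_b * lam + n_w) / (n_b + n_w)
            loglik = float(
                np.sum(
                    np.where(
                        freed,
                        -0.5 * n_b * (np.log(lam) + 1.0) - 0.5 * n_w,
                        -0.5 * (n_b + n_w) * (np.log(w_hat) + 1.0),
                    )
                )
            )
            g_eval = np.where(freed, lam - 1.0, 0.0)
            g_r = w_half @ ((u * g_eval) @ u.T) @ w_half
            fits[r] = (g_r + g_r.T) / 2
            k = r * d - r * (r - 1) // 2
            if n - k - 1 <= 0:
                aicc = np.inf
            else:
                aicc = -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)
            rows.append({"rank": r, "loglik": loglik, "n_params": k, "aicc": aicc})
        return pd.DataFrame(rows).set_index("rank"), fits


@dataclass
class GUncertaintySamples:
    """Replicate G matrices from the sampling distribution of the estimate."""

    replicates: list[SexedG]
    method: str
    seed: int

    def __len__(self) -> int:
        return len(self.replicates)


@dataclass
class GEstimateResults:
    """A fitted sexed G matrix with its rank, error covariance and metadata."""

    model: SexedGModel
    g: SexedG
    g_raw: np.ndarray
    rank: int
    error_cov: np.ndarray
    n_lines: int
    n_reps: int
    aicc: pd.DataFrame
    method: str = METHOD_TAG

    def summary(self) -> str:
        lines = [
            "Sexed G matrix estimate",
            f"  method:    {self.method}",
            f"  traits:    {len(self.g.variables)} sexed variables "
            f"({len(self.g.shared_traits)} shared)",
            f"  design:    {self.n_lines} lines x {self.n_reps} reps",
            f"  rank:      {self.rank} (AICc-selected from "
            f"{len(self.aicc)} candidates)",
            f"  trace(G):  {np.trace(self.g.cov):.6g}",
            "  r_MF diagonal: "
            + ", ".join(
                f"{t}={v:.3f}" for t, v in self.g.r_mf.items()
            ),
        ]
        return "\n".join(lines)

    def sample(self, n: int = 1000, seed: int = 0) -> GUncertaintySamples:
        """Parametric Wishart resampling of the balanced design.

        Draws the between-line and within-line scatter matrices from
        central Wishart distributions at the estimated parameters, then
        re-applies the moment estimator (subtraction, PSD projection and
        truncation to the selected rank) to each draw.
        """
        d = len(self.g.variables)
        if self.n_lines <= d and self.rank >= d:
            raise ValueError(
                "more variables than lines: truncate the rank before sampling"
            )
        rng = np.random.default_rng(seed)
        df_b = self.n_lines - 1
        sigma_b = self.g.cov + self.error_cov / max(self.n_reps, 1)
        jitter = 1e-8 * max(np.trace(sigma_b) / d, 1e-300)
        sigma_b = sigma_b + np.eye(d) * jitter
        w_b = stats.wishart(df=df_b, scale=sigma_b / df_b)
        df_w = self.n_lines * (self.n_reps - 1)
        use_w = df_w >= 1 and np.trace(self.error_cov) > 0
        if use_w:
            scale_w = self.error_cov + np.eye(d) * (
                1e-8 * max(np.trace(self.error_cov) / d, 1e-300)
            )
            w_w = stats.wishart(df=df_w, scale=scale_w / df_w)
        replicates = []
        for _ in range(n):
            s_b = w_b.rvs(random_state=rng)
            g_star = s_b
            if use_w:
                g_star = s_b - w_w.rvs(random_state=rng) / self.n_reps
            g_star = _truncate_rank(_psd_project(g_star), self.rank)
            replicates.append(SexedG(self.g.variables, g_star, validate=False))
        return GUncertaintySamples(replicates, SAMPLER_TAG, seed)


def summarize_over_replicates(
    samples: GUncertaintySamples | Sequence[SexedG],
    statistic: Callable[[SexedG], float],
) -> pd.Series:
    """Median and 2.5%/97.5% quantiles of a scalar functional of G.

    Replicates on which the statistic is undefined (NaN or raising
    ArithmeticError/ValueError) are excluded and counted.
    """
    reps = samples.replicates if isinstance(samples, GUncertaintySamples) else samples
    vals = []
    n_missing = 0
    for g in reps:
        try:
            v = float(statistic(g))
        except (ArithmeticError, ValueError):
            v = np.nan
        if np.isfinite(v):
            vals.append(v)
        else:
            n_missing += 1
    if not vals:
        return pd.Series(
            {"median": np.nan, "q2.5": np.nan, "q97.5": np.nan, "n_missing": n_missing}
        )
    arr = np.array(vals)
    med, lo, hi = np.quantile(arr, [0.5, 0.025, 0.975])  # type-7 interpolation
    return pd.Series({"median": med, "q2.5": lo, "q97.5": hi, "n_missing": n_missing})
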