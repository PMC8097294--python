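"""Selection-response predictions for sexed trait sets.

The two-sex breeder's equation predicts the per-generation change in male
and female trait means from a selection gradient ``beta`` and the full
sexed genetic covariance matrix::

    [dz_M]   1 [ G_M   B  ] [beta_M]
    [dz_F] = - [ B^T  G_F ] [beta_F]
             2

The factor 1/2 reflects that each sex contributes half the autosomal genes
of the next generation.  It is applied to the predicted responses and to
the dimorphism change ``Delta`` (the vector of male-minus-female responses
over shared traits), but *not* to evolvability ``e`` and respondability
``R``, which follow the usual definitions as the response in the direction
of, and the length of the response to, a unit gradient.  Every ratio this
module reports is invariant to that choice.

Closed forms for one- and two-trait cases are provided alongside the
general engine; they agree with it to machine precision and expose which
parts of the matrix drive dimorphism: antagonistic selection sees only the
sex-averaged within-sex block and the symmetric part of B, while
concordant selection sees only the within-sex asymmetry (G_M - G_F)/2 and
the antisymmetric part of B.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .gmatrix import (
    GMatrixError,
    MatrixModification,
    SexedG,
    apply_modification,
    assemble,
)

__all__ = [
    "SelectionGradient",
    "ResponseSummary",
    "SingleTraitParams",
    "TwoTraitParams",
    "predict_response",
    "dimorphism_change_closed_form",
    "d_statistic",
    "single_trait_deltas",
    "concordant_dominance_condition",
    "d_threshold_to_variance_ratio",
    "two_trait_indirect",
    "two_trait_both_selected",
    "conditional_response",
    "modification_ratio_table",
    "summarize_over_gradients",
]

#: eigenvalue floor (relative to the largest) used before inverting G
CONDITIONAL_EIG_FLOOR = 1e-8


@dataclass(frozen=True)
class SelectionGradient:
    """A selection gradient over the variables of a sexed G matrix.

    Units: change in relative fitness per unit log2 expression.  Under the
    ``unit_total`` convention the Euclidean norm over the whole sexed
    vector is 1, so a single-trait antagonistic gradient is (+1/sqrt(2),
    -1/sqrt(2)).
    """

    beta: np.ndarray
    scheme: str  # antagonistic | concordant | custom
    selected_traits: tuple[str, ...] = ()
    norm_convention: str = "unit_total"

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        if self.scheme not in ("antagonistic", "concordant", "custom"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.norm_convention not in ("unit_total", "raw"):
            raise ValueError(f"unknown norm convention {self.norm_convention!r}")
        if self.norm_convention == "unit_total":
            nrm = float(np.linalg.norm(self.beta))
            if abs(nrm - 1.0) > 1e-12:
                raise ValueError(f"unit_total gradient has norm {nrm!r}")

    @staticmethod
    def _build(
        g: SexedG,
        traits: Sequence[str],
        scheme: str,
        normalize: bool,
        strength: float,
    ) -> "SelectionGradient":
        traits = list(traits)
        shared = set(g.shared_traits)
        missing = [t for t in traits if t not in shared]
        if missing:
            raise ValueError(f"traits not shared between sexes: {missing}")
        beta = np.zeros(len(g.variables))
        sign_f = -1.0 if scheme == "antagonistic" else 1.0
        for t in traits:
            beta[g.index_of(t, "M")] = strength
            beta[g.index_of(t, "F")] = sign_f * strength
        if normalize:
            beta /= np.linalg.norm(beta)
        return SelectionGradient(
            beta,
            scheme,
            tuple(traits),
            "unit_total" if normalize else "raw",
        )

    @classmethod
    def antagonistic(
        cls, g: SexedG, traits: Sequence[str], normalize: bool = True, strength: float = 1.0
    ) -> "SelectionGradient":
        """Equal and opposite selection on the sexes (male +, female -)."""
        return cls._build(g, traits, "antagonistic", normalize, strength)

    @classmethod
    def concordant(
        cls, g: SexedG, traits: Sequence[str], normalize: bool = True, strength: float = 1.0
    ) -> "SelectionGradient":
        """Equal selection in the same direction in both sexes."""
        return cls._build(g, traits, "concordant", normalize, strength)

    @classmethod
    def custom(cls, beta: np.ndarray, normalize: bool = False) -> "SelectionGradient":
        beta = np.asarray(beta, dtype=float)
        if normalize:
            beta = beta / np.linalg.norm(beta)
        return cls(beta, "custom", (), "unit_total" if normalize else "raw")

    @property
    def label(self) -> str:
        if self.scheme == "custom":
            return "custom"
        tag = "A" if self.scheme == "antagonistic" else "C"
        return "+".join(self.selected_traits) + f":{tag}"


@dataclass(frozen=True)
class ResponseSummary:
    """Predicted responses and dimorphism summaries for one gradient.

    ``dz`` is the per-variable response (log2 units per generation),
    ``dimorphism_change`` the male-minus-female response per shared trait,
    ``delta_norm`` its Euclidean norm, ``e``/``r`` evolvability and
    respondability, and ``vec_corr`` the Pearson correlation between the
    male and female shared-trait response sub-vectors.
    """

    dz: pd.Series
    dimorphism_change: pd.Series
    e: float
    r: float
    delta_norm: float
    vec_corr: float

    def as_row(self) -> dict:
        return {
            "e": self.e,
            "R": self.r,
            "delta_norm": self.delta_norm,
            "vec_corr": self.vec_corr,
        }


def predict_response(
    g: SexedG,
    grad: SelectionGradient,
    allow_correlation: bool = False,
) -> ResponseSummary:
    """Predict responses to one generation of selection (general engine)."""
    beta = grad.beta
    if beta.shape != (len(g.variables),):
        raise ValueError(
            f"gradient length {beta.shape} does not match {len(g.variables)} variables"
        )
    if not np.any(beta):
        raise ValueError("selection gradient is all zero")
    if g.is_correlation and not allow_correlation:
        raise GMatrixError(
            "g stores correlations; pass allow_correlation=True to override"
        )
    cb = g.cov @ beta
    dz = pd.Series(0.5 * cb, index=g.labels, name="dz")
    shared = g.shared_traits
    delta = np.array(
        [dz.iloc[g.index_of(t, "M")] - dz.iloc[g.index_of(t, "F")] for t in shared]
    )
    dimorphism_change = pd.Series(delta, index=shared, name="delta")
    bb = float(beta @ beta)
    e = float(beta @ cb) / bb
    r = float(np.linalg.norm(cb)) / np.sqrt(bb)
    vec_corr = _shared_vec_corr(g, dz)
    return ResponseSummary(
        dz=dz,
        dimorphism_change=dimorphism_change,
        e=e,
        r=r,
        delta_norm=float(np.linalg.norm(delta)),
        vec_corr=vec_corr,
    )


def _shared_vec_corr(g: SexedG, dz: pd.Series) -> float:
    shared = g.shared_traits
    if len(shared) < 2:
        return np.nan
    dm = np.array([dz.iloc[g.index_of(t, "M")] for t in shared])
    df_ = np.array([dz.iloc[g.index_of(t, "F")] for t in shared])
    if np.std(dm) == 0 or np.std(df_) == 0:
        return np.nan
    return float(np.corrcoef(dm, df_)[0, 1])


def dimorphism_change_closed_form(g: SexedG, grad: SelectionGradient) -> pd.Series:
    """Dimorphism change from the shared-trait blocks only.

    Antagonistic: Delta = (G_bar - B_S) beta_M.  Concordant:
    Delta = ((G_M - G_F)/2 + B_A) beta_M.  Valid when selection acts on
    shared traits only; equals the general engine to machine precision.
    """
    if grad.scheme not in ("antagonistic", "concordant"):
        raise ValueError("closed form defined for antagonistic/concordant schemes only")
    shared = g.shared_traits
    im = [g.index_of(t, "M") for t in shared]
    i_f = [g.index_of(t, "F") for t in shared]
    beta_m = grad.beta[im]
    nonshared_sel = np.delete(grad.beta, im + i_f)
    if np.any(nonshared_sel):
        raise ValueError("closed form requires selection on shared traits only")
    gm = g.cov[np.ix_(im, im)]
    gf = g.cov[np.ix_(i_f, i_f)]
    b = g.cov[np.ix_(im, i_f)]
    if grad.scheme == "antagonistic":
        mat = (gm + gf) / 2.0 - (b + b.T) / 2.0
    else:
        mat = (gm - gf) / 2.0 + (b - b.T) / 2.0
    return pd.Series(mat @ beta_m, index=shared, name="delta")


# -- one-trait closed forms --------------------------------------------


def d_statistic(m: float, f: float) -> float:
    """Ratio of the geometric to the arithmetic mean of the sex variances.

    Equals 1 when m == f and decays slowly with variance asymmetry: a 2:1
    ratio gives 0.94, and d is not halved until the ratio is nearly 14:1.
    """
    if m <= 0 or f <= 0:
        raise ValueError("variances must be positive")
    return float(np.sqrt(m * f) / ((m + f) / 2.0))


@dataclass(frozen=True)
class SingleTraitParams:
    """Sex-specific genetic parameters of one trait."""

    m: float
    f: float
    b: float
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.m < 0 or self.f < 0:
            raise ValueError("variances must be nonnegative")
        if self.b**2 > self.m * self.f * (1 + 1e-12):
            raise ValueError("|b| exceeds sqrt(m*f)")

    @property
    def g_bar(self) -> float:
        return (self.m + self.f) / 2.0

    @property
    def d(self) -> float:
        return d_statistic(self.m, self.f)

    @property
    def r_mf(self) -> float:
        mf = self.m * self.f
        if mf == 0:
            raise ValueError("r_MF undefined when m*f == 0")
        return self.b / np.sqrt(mf)


def single_trait_deltas(p: SingleTraitParams) -> tuple[float, float]:
    """Dimorphism change of one trait under antagonistic and concordant selection.

    Returns ``(delta_A, delta_C)`` with delta_A = beta (g_bar - b)
    = beta g_bar (1 - d r_MF) and delta_C = beta (m - f)/2, whose
    magnitude equals beta g_bar sqrt(1 - d^2).
    """
    delta_a = p.beta * (p.g_bar - p.b)
    delta_c = p.beta * (p.m - p.f) / 2.0
    return float(delta_a), float(delta_c)


def concordant_dominance_condition(r_mf: float) -> float:
    """Threshold on d below which concordant selection changes dimorphism faster.

    Concordant selection of equal strength outpaces antagonistic selection
    whenever d < 2 r_MF / (r_MF^2 + 1); the condition is easier to satisfy
    the larger the intersexual correlation.
    """
    if not 0 < r_mf <= 1:
        raise ValueError("condition stated for r_MF in (0, 1]")
    return float(2.0 * r_mf / (r_mf**2 + 1.0))


def d_threshold_to_variance_ratio(d: float) -> float:
    """Variance ratio rho >= 1 at which d(rho) = 2 sqrt(rho)/(1+rho) equals ``d``.

    Solves the quadratic s^2 - (2/d) s + 1 = 0 in s = sqrt(rho), taking the
    root >= 1.
    """
    if not 0 < d <= 1:
        raise ValueError("d must be in (0, 1]")
    s = (1.0 + np.sqrt(1.0 - d**2)) / d
    return float(s**2)


# -- two-trait closed forms --------------------------------------------


@dataclass(frozen=True)
class TwoTraitParams:
    """Unit-variance two-trait genetic correlation structure.

    ``r_m12``/``r_f12`` are the within-sex cross-trait correlations,
    ``r_mf1``/``r_mf2`` the homologous cross-sex correlations, and
    ``c12``/``c21`` the off-diagonal cross-sex correlations with
    ``c12 = corr(trait 1 in males, trait 2 in females)`` and
    ``c21 = corr(trait 2 in males, trait 1 in females)``.
    """

    r_m12: float
    r_f12: float
    r_mf1: float
    r_mf2: float
    c12: float
    c21: float
    beta: float = 1.0

    def __post_init__(self) -> None:
        for name in ("r_m12", "r_f12", "r_mf1", "r_mf2", "c12", "c21"):
            v = getattr(self, name)
            if abs(v) > 1:
                raise ValueError(f"{name}={v} outside [-1, 1]")

    def to_sexed_g(self) -> SexedG:
        gm = np.array([[1.0, self.r_m12], [self.r_m12, 1.0]])
        gf = np.array([[1.0, self.r_f12], [self.r_f12, 1.0]])
        b = np.array([[self.r_mf1, self.c12], [self.c21, self.r_mf2]])
        return assemble(gm, gf, b, ["z1", "z2"], ["z1", "z2"], is_correlation=True)

    @property
    def r_w_bar(self) -> float:
        return (self.r_m12 + self.r_f12) / 2.0

    @property
    def r_b_bar(self) -> float:
        return (self.c12 + self.c21) / 2.0


def two_trait_indirect(p: TwoTraitParams, scheme: str) -> float:
    """Indirect dimorphism change of trait 2 when only trait 1 is selected.

    Antagonistic: beta [ (r_m12 + r_f12)/2 - (c12 + c21)/2 ].
    Concordant:   beta [ (r_m12 - r_f12)/2 + (c21 - c12)/2 ].
    """
    if scheme == "antagonistic":
        return float(p.beta * (p.r_w_bar - p.r_b_bar))
    if scheme == "concordant":
        return float(p.beta * ((p.r_m12 - p.r_f12) / 2.0 + (p.c21 - p.c12) / 2.0))
    raise ValueError(f"unknown scheme {scheme!r}")


def two_trait_both_selected(p: TwoTraitParams, scheme: str) -> np.ndarray:
    """Dimorphism change per trait when both unit-variance traits are selected.

    Antagonistic (beta, beta, -beta, -beta): per trait t,
    beta [1 - r_MF_t + r_w_bar - r_b_bar].  Concordant (all +beta):
    (beta/2) [(r_m12 - r_f12) +/- (c12 - c21)], the sign of the B-asymmetry
    term alternating between the traits; with all variances equal there is
    no direct response, only these asymmetry-driven indirect ones.
    """
    if scheme == "antagonistic":
        common = p.r_w_bar - p.r_b_bar
        return np.array(
            [
                p.beta * (1.0 - p.r_mf1 + common),
                p.beta * (1.0 - p.r_mf2 + common),
            ]
        )
    if scheme == "concordant":
        dw = p.r_m12 - p.r_f12
        db = p.c12 - p.c21
        return np.array(
            [p.beta / 2.0 * (dw + db), p.beta / 2.0 * (dw - db)]
        )
    raise ValueError(f"unknown scheme {scheme!r}")


def both_selected_gradient(p: TwoTraitParams, scheme: str) -> SelectionGradient:
    """Raw-norm gradient matching :func:`two_trait_both_selected`."""
    sign_f = -1.0 if scheme == "antagonistic" else 1.0
    beta = p.beta * np.array([1.0, 1.0, sign_f, sign_f])
    return SelectionGradient.custom(beta)


# -- conditional responses ---------------------------------------------


def conditional_response(g: SexedG, grad: SelectionGradient) -> ResponseSummary:
    """Response when off-gradient directions are held fixed by stabilizing selection.

    The response is constrained to the direction of ``beta`` with magnitude
    set by the conditional evolvability c(beta) = (b_hat' G^-1 b_hat)^-1
    for the unit gradient direction b_hat; c(beta) <= e(beta) always.
    Rank-deficient matrices are regularized by flooring eigenvalues at
    1e-8 of the largest before inversion.
    """
    beta = grad.beta
    if not np.any(beta):
        raise ValueError("selection gradient is all zero")
    bhat = beta / np.linalg.norm(beta)
    evals, evecs = np.linalg.eigh((g.cov + g.cov.T) / 2)
    floor = CONDITIONAL_EIG_FLOOR * max(evals[-1], 0.0)
    if floor <= 0:
        raise GMatrixError("matrix has no positive eigenvalues; cannot condition")
    evals = np.clip(evals, floor, None)
    ginv_b = (evecs / evals) @ (evecs.T @ bhat)
    c = 1.0 / float(bhat @ ginv_b)
    dz_vec = 0.5 * c * bhat * np.linalg.norm(beta)
    dz = pd.Series(dz_vec, index=g.labels, name="dz")
    shared = g.shared_traits
    delta = np.array(
        [dz.iloc[g.index_of(t, "M")] - dz.iloc[g.index_of(t, "F")] for t in shared]
    )
    return ResponseSummary(
        dz=dz,
        dimorphism_change=pd.Series(delta, index=shared, name="delta"),
        e=c,
        r=c,
        delta_norm=float(np.linalg.norm(delta)),
        vec_corr=_shared_vec_corr(g, dz),
    )


# -- modification experiments ------------------------------------------


def modification_ratio_table(
    g: SexedG,
    grads: Iterable[SelectionGradient],
    mods: Iterable[MatrixModification | str] = tuple(MatrixModification),
) -> pd.DataFrame:
    """Ratio of dimorphism-change norms, modified over unmodified matrix.

    One row per (gradient, modification) with ``e``, ``R``,
    ``delta_norm`` from the modified matrix and ``ratio`` =
    ||Delta||(modified) / ||Delta||(unmodified); NaN when the unmodified
    norm is zero.  Antagonistic ratios are exactly 1 under any combination
    of the averaging and B-symmetrizing substitutions; concordant ratios
    are exactly 0 once both asymmetries are removed.
    """
    rows = []
    for grad in grads:
        base = predict_response(g, grad, allow_correlation=True)
        for mod in mods:
            mod = MatrixModification(mod)
            g_mod = apply_modification(g, mod)
            resp = predict_response(g_mod, grad, allow_correlation=True)
            ratio = (
                resp.delta_norm / base.delta_norm if base.delta_norm > 0 else np.nan
            )
            rows.append(
                {
                    "gradient": grad.label,
                    "scheme": grad.scheme,
                    "modification": mod.value,
                    **resp.as_row(),
                    "ratio": ratio,
                }
            )
    return pd.DataFrame(rows)


def summarize_over_gradients(
    g: SexedG, grads: Iterable[SelectionGradient]
) -> pd.DataFrame:
    """One row of e, R, ||Delta||, vec_corr per gradient (Table-3-like)."""
    rows = []
    for grad in grads:
        resp = predict_response(g, grad, allow_correlation=True)
        rows.append({"gradient": grad.label, "scheme": grad.scheme, **resp.as_row()})
    return pd.DataFrame(rows)
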