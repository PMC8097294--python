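"""Sex-specific genetic covariance matrices.

A full genetic covariance matrix over trait copies expressed in males and
females is the object the two-sex breeder's equation acts on.  It is stored
with the male block first::

    [ G_M   B  ]
    [ B^T  G_F ]

where ``G_M`` and ``G_F`` are the within-sex covariance blocks and ``B``
holds covariances between traits expressed in males (rows) and traits
expressed in females (columns).  ``B`` is defined over *shared* traits,
i.e. trait labels present in both sexes; traits expressed in one sex only
(e.g. male-biased expression combinations) have no cross-sex covariance by
construction.  The diagonal of ``B`` divided by the geometric mean of the
corresponding within-sex variances gives the intersexual genetic
correlation ``r_MF``.

``B`` need not be symmetric: alleles may have different magnitudes of
effect in each sex, so cov(trait i in males, trait j in females) can differ
from cov(trait j in males, trait i in females).  Its symmetric and
antisymmetric parts, ``B_S = (B + B^T)/2`` and ``B_A = (B - B^T)/2``,
govern the response of dimorphism to antagonistic and concordant selection
respectively, which is why the matrix-modification experiments below
substitute them (and the sex-averaged within-sex block ``G_bar``) into the
full matrix.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SexedVariable",
    "SexedG",
    "MatrixModification",
    "GMatrixError",
    "assemble",
    "extract_blocks",
    "apply_modification",
    "bend",
    "read_g_csv",
    "write_g_csv",
]

#: relative symmetry tolerance for validation
SYMMETRY_RTOL = 1e-10
#: eigenvalues below -PSD_RTOL * lambda_max fail the PSD check
PSD_RTOL = 1e-8


class GMatrixError(ValueError):
    """Raised when a sexed covariance matrix fails validation."""


@dataclass(frozen=True)
class SexedVariable:
    """A trait copy expressed in one sex."""

    trait: str
    sex: str  # "M" or "F"

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise GMatrixError(f"sex must be 'M' or 'F', got {self.sex!r}")

    @property
    def label(self) -> str:
        return f"{self.trait}:{self.sex}"

    @classmethod
    def from_label(cls, label: str) -> "SexedVariable":
        trait, _, sex = label.rpartition(":")
        if not trait:
            raise GMatrixError(f"cannot parse variable label {label!r}")
        return cls(trait, sex)


class MatrixModification(str, enum.Enum):
    """The structured substitutions used to probe which asymmetries matter.

    ``avg_G`` replaces the shared-trait parts of both within-sex blocks by
    their average; ``sym_B`` replaces B by its symmetric part; ``zero_B``
    removes the cross-sex block entirely.  The combined modes compose the
    single substitutions.
    """

    none = "none"
    avg_G = "avg_G"
    sym_B = "sym_B"
    zero_B = "zero_B"
    avg_G_sym_B = "avg_G_sym_B"
    avg_G_zero_B = "avg_G_zero_B"


@dataclass(frozen=True)
class SexedG:
    """A validated genetic covariance matrix over sexed trait copies.

    Parameters
    ----------
    variables
        Ordered tuple of :class:`SexedVariable`; all male variables first,
        then all female variables; within a sex, shared traits precede
        sex-limited ones.
    cov
        Square covariance (or correlation) matrix in that variable order,
        in squared log2-expression units (unitless if ``is_correlation``).
    is_correlation
        Whether ``cov`` stores correlations (unit diagonal enforced).
    """

    variables: tuple[SexedVariable, ...]
    cov: np.ndarray
    is_correlation: bool = False
    validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        cov = np.asarray(self.cov, dtype=float)
        object.__setattr__(self, "cov", cov)
        object.__setattr__(self, "variables", tuple(self.variables))
        if self.validate:
            self._validate()

    # -- validation ---------------------------------------------------
    def _validate(self) -> None:
        k = len(self.variables)
        if self.cov.shape != (k, k):
            raise GMatrixError(
                f"covariance shape {self.cov.shape} does not match "
                f"{k} variables"
            )
        if len(set(self.variables)) != k:
            raise GMatrixError("duplicate (trait, sex) variables")
        sexes = [v.sex for v in self.variables]
        if "F" in sexes and "M" in sexes:
            first_f = sexes.index("F")
            if "M" in sexes[first_f:]:
                raise GMatrixError("male variables must precede female ones")
        scale = np.max(np.abs(self.cov)) or 1.0
        if not np.allclose(self.cov, self.cov.T, rtol=0, atol=SYMMETRY_RTOL * scale):
            raise GMatrixError("matrix is not symmetric")
        evals = np.linalg.eigvalsh((self.cov + self.cov.T) / 2)
        lam_max = max(evals[-1], 0.0)
        if evals[0] < -PSD_RTOL * max(lam_max, 1e-300):
            raise GMatrixError(
                f"matrix is not positive semidefinite: eigenvalue {evals[0]:.3e} "
                f"(largest {lam_max:.3e})"
            )
        if self.is_correlation and not np.allclose(np.diag(self.cov), 1.0, atol=1e-8):
            raise GMatrixError("correlation matrix must have unit diagonal")

    # -- structure ----------------------------------------------------
    @property
    def labels(self) -> list[str]:
        return [v.label for v in self.variables]

    @property
    def male_index(self) -> np.ndarray:
        return np.array([i for i, v in enumerate(self.variables) if v.sex == "M"], dtype=int)

    @property
    def female_index(self) -> np.ndarray:
        return np.array([i for i, v in enumerate(self.variables) if v.sex == "F"], dtype=int)

    @property
    def male_traits(self) -> list[str]:
        return [v.trait for v in self.variables if v.sex == "M"]

    @property
    def female_traits(self) -> list[str]:
        return [v.trait for v in self.variables if v.sex == "F"]

    @property
    def shared_traits(self) -> list[str]:
        female = set(self.female_traits)
        return [t for t in self.male_traits if t in female]

    def index_of(self, trait: str, sex: str) -> int:
        return self.variables.index(SexedVariable(trait, sex))

    @property
    def g_m(self) -> np.ndarray:
        """Within-sex covariance block over all male variables."""
        im = self.male_index
        return self.cov[np.ix_(im, im)]

    @property
    def g_f(self) -> np.ndarray:
        im = self.female_index
        return self.cov[np.ix_(im, im)]

    @property
    def cross(self) -> np.ndarray:
        """Full cross-sex block (all male rows x all female columns)."""
        return self.cov[np.ix_(self.male_index, self.female_index)]

    @property
    def b(self) -> np.ndarray:
        """Cross-sex block over shared traits (male rows, female columns)."""
        shared = self.shared_traits
        im = [self.index_of(t, "M") for t in shared]
        i_f = [self.index_of(t, "F") for t in shared]
        return self.cov[np.ix_(im, i_f)]

    # -- per-trait genetic summaries ----------------------------------
    @property
    def m(self) -> pd.Series:
        """Male genetic variances of shared traits."""
        return pd.Series(
            [self.cov[self.index_of(t, "M"), self.index_of(t, "M")] for t in self.shared_traits],
            index=self.shared_traits,
            name="m",
        )

    @property
    def f(self) -> pd.Series:
        return pd.Series(
            [self.cov[self.index_of(t, "F"), self.index_of(t, "F")] for t in self.shared_traits],
            index=self.shared_traits,
            name="f",
        )

    @property
    def b_diag(self) -> pd.Series:
        """Cross-sex covariance of homologous shared traits."""
        return pd.Series(np.diag(self.b), index=self.shared_traits, name="b")

    @property
    def r_mf(self) -> pd.Series:
        """Intersexual genetic correlation per shared trait."""
        denom = np.sqrt(self.m.values * self.f.values)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(denom > 0, self.b_diag.values / denom, np.nan)
        return pd.Series(r, index=self.shared_traits, name="r_mf")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cov, index=self.labels, columns=self.labels)


def assemble(
    g_m: np.ndarray,
    g_f: np.ndarray,
    b: np.ndarray,
    male_traits: list[str],
    female_traits: list[str],
    is_correlation: bool = False,
    cross: np.ndarray | None = None,
) -> SexedG:
    """Assemble a full sexed covariance matrix from its blocks.

    ``b`` must be square over the shared traits (rows male, columns
    female, in the order the shared traits appear in ``male_traits`` /
    ``female_traits``).  Variables are placed male block first; within a
    block, shared traits precede sex-limited ones.  Cross-sex covariances
    involving sex-limited traits default to zero; pass ``cross`` (the
    full male x female block, in the given trait orders) to supply them,
    in which case its shared part must agree with ``b``.
    """
    g_m = np.asarray(g_m, dtype=float)
    g_f = np.asarray(g_f, dtype=float)
    b = np.asarray(b, dtype=float)
    if g_m.shape != (len(male_traits),) * 2:
        raise GMatrixError("G_M dimensions do not match male trait labels")
    if g_f.shape != (len(female_traits),) * 2:
        raise GMatrixError("G_F dimensions do not match female trait labels")
    female_set = set(female_traits)
    shared = [t for t in male_traits if t in female_set]
    if b.shape != (len(shared),) * 2:
        raise GMatrixError(
            f"B must be {len(shared)}x{len(shared)} over shared traits, got {b.shape}"
        )
    # canonical order: shared first within each sex block
    m_order = shared + [t for t in male_traits if t not in female_set]
    male_set = set(male_traits)
    f_shared = [t for t in female_traits if t in male_set]
    if f_shared != shared:
        # same set guaranteed; enforce same ordering convention
        shared_order = {t: i for i, t in enumerate(shared)}
        f_shared = sorted(f_shared, key=shared_order.get)
    f_order = shared + [t for t in female_traits if t not in male_set]

    pm = [male_traits.index(t) for t in m_order]
    pf = [female_traits.index(t) for t in f_order]
    g_m = g_m[np.ix_(pm, pm)]
    g_f = g_f[np.ix_(pf, pf)]

    km, kf, ks = len(m_order), len(f_order), len(shared)
    cov = np.zeros((km + kf, km + kf))
    cov[:km, :km] = g_m
    cov[km:, km:] = g_f
    if cross is not None:
        cross = np.asarray(cross, dtype=float)
        if cross.shape != (km, kf):
            raise GMatrixError(f"cross block must be {km}x{kf}, got {cross.shape}")
        cross = cross[np.ix_(pm, pf)]
        if not np.array_equal(cross[:ks, :ks], b):
            raise GMatrixError("cross block disagrees with B over shared traits")
        cov[:km, km:] = cross
        cov[km:, :km] = cross.T
    else:
        cov[:ks, km : km + ks] = b
        cov[km : km + ks, :ks] = b.T
    variables = [SexedVariable(t, "M") for t in m_order] + [
        SexedVariable(t, "F") for t in f_order
    ]
    return SexedG(tuple(variables), cov, is_correlation=is_correlation)


def extract_blocks(g: SexedG) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Return ``(G_M, G_F, B, shared_traits)`` in the matrix's stored order."""
    return g.g_m, g.g_f, g.b, g.shared_traits


def _shared_indices(g: SexedG) -> tuple[list[int], list[int]]:
    shared = g.shared_traits
    return (
        [g.index_of(t, "M") for t in shared],
        [g.index_of(t, "F") for t in shared],
    )


def apply_modification(g: SexedG, mod: MatrixModification | str) -> SexedG:
    """Apply one of the structured substitutions to a sexed G matrix.

    Symmetrizing B in isolation can make the full matrix indefinite; since
    the downstream response predictions are still well defined (and the
    substitution is exactly the point of the experiment), a failed PSD
    check on a modified matrix is reported as a warning rather than an
    error.
    """
    mod = MatrixModification(mod)
    if mod is MatrixModification.none:
        return g
    if not g.shared_traits:
        raise GMatrixError(f"modification {mod.value!r} needs shared traits")
    cov = g.cov.copy()
    im, i_f = _shared_indices(g)
    if mod in (
        MatrixModification.avg_G,
        MatrixModification.avg_G_sym_B,
        MatrixModification.avg_G_zero_B,
    ):
        gm_s = cov[np.ix_(im, im)]
        gf_s = cov[np.ix_(i_f, i_f)]
        g_bar = (gm_s + gf_s) / 2.0
        cov[np.ix_(im, im)] = g_bar
        cov[np.ix_(i_f, i_f)] = g_bar
    if mod in (MatrixModification.sym_B, MatrixModification.avg_G_sym_B):
        b = cov[np.ix_(im, i_f)]
        b_s = (b + b.T) / 2.0
        cov[np.ix_(im, i_f)] = b_s
        cov[np.ix_(i_f, im)] = b_s.T
    if mod in (MatrixModification.zero_B, MatrixModification.avg_G_zero_B):
        mi, fi = g.male_index, g.female_index
        cov[np.ix_(mi, fi)] = 0.0
        cov[np.ix_(fi, mi)] = 0.0
    try:
        return SexedG(g.variables, cov, is_correlation=g.is_correlation)
    except GMatrixError as err:
        warnings.warn(
            f"modified matrix ({mod.value}) failed validation: {err}; "
            "returning unvalidated matrix",
            RuntimeWarning,
            stacklevel=2,
        )
        return SexedG(g.variables, cov, is_correlation=g.is_correlation, validate=False)


def bend(g: SexedG) -> SexedG:
    """Project to the nearest PSD matrix, rescaling to preserve the trace.

    Negative eigenvalues are clipped at zero and the spectrum rescaled so
    the total genetic variance (trace) is unchanged.  Off by default in
    every pipeline stage; offered for indefinite estimates.
    """
    evals, evecs = np.linalg.eigh((g.cov + g.cov.T) / 2)
    clipped = np.clip(evals, 0.0, None)
    total = clipped.sum()
    if total > 0 and evals.sum() > 0:
        clipped *= evals.sum() / total
    cov = (evecs * clipped) @ evecs.T
    cov = (cov + cov.T) / 2
    return SexedG(g.variables, cov, is_correlation=False)


# -- external interface: G matrix CSV + JSON sidecar -------------------


def write_g_csv(g: SexedG, path: str | Path, meta: dict | None = None) -> None:
    """Write a sexed G matrix as CSV with ``trait:sex`` labels.

    A JSON sidecar (``<path>.json``) records ``is_correlation`` plus any
    caller-supplied provenance.  Values are written with 17 significant
    digits so the round trip is bit exact.
    """
    path = Path(path)
    df = g.to_frame()
    df.to_csv(path, float_format="%.17g")
    sidecar = {"is_correlation": g.is_correlation, "units": "log2_expression_sq"}
    sidecar.update(meta or {})
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_g_csv(path: str | Path) -> SexedG:
    path = Path(path)
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if list(df.index) != list(df.columns):
        raise GMatrixError(f"{path}: row and column labels differ")
    variables = tuple(SexedVariable.from_label(lab) for lab in df.index)
    sidecar = Path(str(path) + ".json")
    is_corr = False
    if sidecar.exists():
        is_corr = bool(json.loads(sidecar.read_text()).get("is_correlation", False))
    return SexedG(variables, df.values, is_correlation=is_corr)
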