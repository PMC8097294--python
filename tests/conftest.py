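"""Shared fixtures: random sexed matrices and small synthetic panels."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dimorph.gmatrix import SexedG, SexedVariable


def random_sexed_g(
    n_shared: int,
    rng: np.random.Generator,
    n_male_only: int = 0,
    n_female_only: int = 0,
    scale: float = 1.0,
) -> SexedG:
    """A random valid (PSD) sexed covariance matrix."""
    d = 2 * n_shared + n_male_only + n_female_only
    a = rng.standard_normal((d, d + 2))
    cov = a @ a.T * (scale / (d + 2))
    shared = [f"T{i + 1}" for i in range(n_shared)]
    male = shared + [f"M{i + 1}" for i in range(n_male_only)]
    female = shared + [f"F{i + 1}" for i in range(n_female_only)]
    variables = tuple(
        [SexedVariable(t, "M") for t in male] + [SexedVariable(t, "F") for t in female]
    )
    return SexedG(variables, cov)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_panel():
    """One study-sized panel with truth, shared across tests (read-only)."""
    from dimorph.simulate import make_scenario, simulate_panel

    return simulate_panel(make_scenario("default", seed=101))


@pytest.fixture(scope="session")
def default_summaries(default_panel):
    from dimorph.genewise import gene_summaries

    dataset, _ = default_panel
    summary, lm = gene_summaries(dataset)
    return summary, lm


def rep_scores_from_array(
    z: np.ndarray, variables: tuple[SexedVariable, ...]
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Build a (line, sex, rep)-indexed score frame from an (L, R, d) array.

    Inverse of SexedGModel's internal layout; used to feed planted
    trait-level data to the estimator.
    """
    L, R, d = z.shape
    assert d == len(variables)
    lines = [f"L{i + 1:03d}" for i in range(L)]
    reps = [str(r + 1) for r in range(R)]
    traits = sorted({v.trait for v in variables}, key=[v.trait for v in variables].index)
    trait_sexes = {}
    for t in traits:
        sexes = {v.sex for v in variables if v.trait == t}
        trait_sexes[t] = "both" if len(sexes) == 2 else next(iter(sexes))
    rows = {}
    for li, line in enumerate(lines):
        for ri, rep in enumerate(reps):
            for sex in ("M", "F"):
                key = (line, sex, rep)
                vals = {}
                for vi, v in enumerate(variables):
                    if v.sex == sex:
                        vals[v.trait] = z[li, ri, vi]
                rows.setdefault(key, {}).update(vals)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=traits)
    df.index = pd.MultiIndex.from_tuples(df.index, names=["line", "sex", "rep"])
    return df, trait_sexes


def simulate_trait_scores(
    g: SexedG,
    error_var: float,
    n_lines: int,
    n_reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(L, R, d) replicate sexed vectors with genetic covariance ``g``."""
    d = len(g.variables)
    evals, evecs = np.linalg.eigh(g.cov)
    a = evecs * np.sqrt(np.clip(evals, 0.0, None))
    gvals = rng.standard_normal((n_lines, d)) @ a.T
    noise = rng.standard_normal((n_lines, n_reps, d)) * np.sqrt(error_var)
    return gvals[:, None, :] + noise
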