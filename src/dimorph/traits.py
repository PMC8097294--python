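"""Low-dimensional expression traits from bias-class PCA.

With only ~40 lines, a genetic covariance matrix can be estimated for at
most a handful of traits.  The trait set is therefore built from
principal components computed within each sex-bias class of genes:

* unbiased (UB) genes: PCA on the covariance matrix of line-sex averages
  (the 2L line-by-sex mean vectors pooled as observations); the male and
  female scores of each component are computed from the same shared
  loadings, so the dimorphism of a UB trait is loadings' (male - female
  gene means);
* male-biased (MB) and female-biased (FB) genes: PCA of the line means in
  the dominant sex only; scores exist only for that sex (the subordinate
  sex typically shows no genetic variance for these combinations, and its
  scores are deliberately not constructed).

The default trait set keeps 2 MB, 2 FB and 4 UB components, giving 12
sexed traits (4 shared between sexes, 2 male-only, 2 female-only).
Components use covariance (not correlation) PCA, centered at the column
means of the observation set, and are oriented so the largest-magnitude
loading of each component is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genewise import SEXES, ExpressionDataset, LineMeanTable

__all__ = ["TraitScoreTable", "class_pca", "assemble_trait_set", "score_samples"]

DEFAULT_TRAIT_SPEC = {"MB": 2, "FB": 2, "UB": 4}


def _orient(loadings: np.ndarray) -> np.ndarray:
    """Flip each component so its largest-|loading| entry is positive."""
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    return loadings * flip


def class_pca(
    lm: LineMeanTable,
    gene_ids: Sequence[str],
    bias_class: str,
    n_components: int,
    pooled_sexes: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, np.ndarray]:
    """Covariance PCA of one bias class.

    Returns ``(loadings, scores, center, explained_variance)``.  For the
    UB class the observations are the line-sex mean vectors (2L rows when
    ``pooled_sexes``, else the L sex-averaged rows) and scores are
    computed for both sexes from the shared loadings; for MB/FB the
    observations are the dominant-sex line means and scores exist for
    that sex only.
    """
    if bias_class not in ("MB", "FB", "UB"):
        raise ValueError(f"unknown bias class {bias_class!r}")
    idx = [lm.gene_ids.index(g) for g in gene_ids]
    if len(idx) < n_components:
        raise ValueError(
            f"{bias_class}: {len(idx)} genes cannot support {n_components} components"
        )
    male = lm.male()[idx].T  # (L, n_genes)
    female = lm.female()[idx].T
    if bias_class == "UB":
        obs = np.vstack([male, female]) if pooled_sexes else (male + female) / 2.0
    elif bias_class == "MB":
        obs = male
    else:
        obs = female
    if not np.isfinite(obs).all():
        raise ValueError(f"{bias_class}: missing line means; screen/filter first")
    if obs.shape[0] < n_components:
        raise ValueError(f"{bias_class}: fewer observations than components")
    center = obs.mean(axis=0)
    centered = obs - center
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    rank = int((svals > svals[0] * 1e-12).sum()) if svals.size else 0
    if n_components > rank:
        raise ValueError(
            f"{bias_class}: requested {n_components} components, rank is {rank}"
        )
    load = _orient(vt[:n_components].T)  # (n_genes, k)
    expl = (svals[:n_components] ** 2) / (obs.shape[0] - 1)
    names = [f"{bias_class}{j + 1}" for j in range(n_components)]
    loadings = pd.DataFrame(load, index=list(gene_ids), columns=names)
    center_s = pd.Series(center, index=list(gene_ids), name="center")
    rows = {}
    if bias_class in ("UB", "MB"):
        for li, line in enumerate(lm.lines):
            rows[(line, "M")] = (male[li] - center) @ load
    if bias_class in ("UB", "FB"):
        for li, line in enumerate(lm.lines):
            rows[(line, "F")] = (female[li] - center) @ load
    scores = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    scores.index = pd.MultiIndex.from_tuples(scores.index, names=["line", "sex"])
    return loadings, scores, center_s, expl


@dataclass
class TraitScoreTable:
    """Line-level (and optionally replicate-level) sexed trait scores.

    ``line_scores`` is indexed by (line, sex) with one column per trait;
    entries are NaN for the sex in which a biased-class trait is not
    defined.  ``loadings``/``centers`` keep enough information to score
    new samples of the same genes.
    """

    line_scores: pd.DataFrame
    loadings: dict[str, pd.DataFrame]
    centers: dict[str, pd.Series]
    class_of_trait: dict[str, str]
    trait_sexes: dict[str, str]  # trait -> "M" | "F" | "both"
    explained_variance: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def traits(self) -> list[str]:
        return list(self.line_scores.columns)

    @property
    def shared_traits(self) -> list[str]:
        return [t for t in self.traits if self.trait_sexes[t] == "both"]


def assemble_trait_set(
    lm: LineMeanTable,
    bias_class: Mapping[str, str] | pd.Series,
    spec: Mapping[str, int] = DEFAULT_TRAIT_SPEC,
    pooled_sexes: bool = True,
) -> TraitScoreTable:
    """Build the sexed trait table from per-class PCAs.

    ``bias_class`` maps gene id -> MB/FB/UB.  The default spec yields 12
    sexed traits; biased-class scores for the subordinate sex are not
    constructed.
    """
    bias_class = pd.Series(dict(bias_class))
    loadings: dict[str, pd.DataFrame] = {}
    centers: dict[str, pd.Series] = {}
    class_of_trait: dict[str, str] = {}
    trait_sexes: dict[str, str] = {}
    expl: dict[str, np.ndarray] = {}
    pieces = []
    for cls, k in spec.items():
        if k == 0:
            continue
        gene_ids = [g for g in lm.gene_ids if bias_class.get(g) == cls]
        load, scores, center, ev = class_pca(lm, gene_ids, cls, k, pooled_sexes)
        loadings[cls] = load
        centers[cls] = center
        expl[cls] = ev
        pieces.append(scores)
        for t in load.columns:
            class_of_trait[t] = cls
            trait_sexes[t] = {"MB": "M", "FB": "F", "UB": "both"}[cls]
    if not pieces:
        raise ValueError("empty trait spec")
    full_index = pd.MultiIndex.from_product(
        [lm.lines, list(SEXES)], names=["line", "sex"]
    )
    line_scores = pd.concat(pieces, axis=1).reindex(full_index)
    return TraitScoreTable(
        line_scores=line_scores,
        loadings=loadings,
        centers=centers,
        class_of_trait=class_of_trait,
        trait_sexes=trait_sexes,
        explained_variance=expl,
    )


def score_samples(table: TraitScoreTable, dataset: ExpressionDataset) -> pd.DataFrame:
    """Replicate-level trait scores from the saved loadings.

    Projects each chip (line, sex, rep) onto the stored class loadings,
    using the same centering as the PCA; traits not defined for a chip's
    sex are NaN.  Single-probe data only (probe effects are a line-mean
    concern).
    """
    if dataset.samples["probe"].nunique() > 1:
        raise ValueError("replicate scoring supports single-probe data only")
    gene_pos = {g: i for i, g in enumerate(dataset.gene_ids)}
    out = {}
    for cls, load in table.loadings.items():
        try:
            idx = [gene_pos[g] for g in load.index]
        except KeyError as err:
            raise KeyError(f"dataset lacks gene {err} used by {cls} loadings") from err
        vals = dataset.values[idx]  # (n_genes, n_samples)
        centered = vals - table.centers[cls].values[:, None]
        scores = centered.T @ load.values  # (n_samples, k)
        for j, t in enumerate(load.columns):
            col = scores[:, j].copy()
            sex_ok = (
                np.ones(len(col), bool)
                if table.trait_sexes[t] == "both"
                else (dataset.samples["sex"] == table.trait_sexes[t]).values
            )
            col[~sex_ok] = np.nan
            out[t] = col
    df = pd.DataFrame(out)
    df.index = pd.MultiIndex.from_frame(
        dataset.samples[["line", "sex", "rep"]]
    )
    return df[table.traits]
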