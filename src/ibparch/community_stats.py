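"""Community composition tables, Bray–Curtis dissimilarity and PERMANOVA.

The composition matrix is samples x taxa (read counts or RPKM). Rows are
closed to proportions by default before Bray–Curtis, the convention of
vegan-style community ecology. PERMANOVA is Anderson's distance-based
one-way formulation: with n samples in a groups,

    SS_total = (1/n)   * sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    pseudo-F = (SS_between/(a-1)) / (SS_within/(n-a)),  R^2 = SS_between/SS_total

and the p-value comes from whole-sample permutations of the group labels:
p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations). The permutation stream
is seeded and reproducible.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .model import GeneRecord, PermanovaResult, SampleMeta, TaxonomyRecord

logger = logging.getLogger(__name__)

#: Default permutation seed: the start date of the drift the samples came from.
DEFAULT_SEED = 20200213

MEASURES = ("braycurtis", "euclidean", "jaccard")


def composition_matrix(
    genes: Iterable[GeneRecord],
    taxonomy_by_gene: Mapping[str, TaxonomyRecord],
    samples: Mapping[str, SampleMeta],
    rank: str = "order",
    values: str = "count",
    rpkm_values: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Samples x taxa composition table and the sample -> environment map.

    ``values`` is ``count`` (one unit per gene) or ``rpkm`` (requires
    ``rpkm_values``). Genes without a taxon at the rank fall into an
    ``unclassified`` column. Zero-total samples are kept in the table but
    flagged; dissimilarity computations exclude them.
    """
    cells: dict[tuple[str, str], float] = {}
    for g in genes:
        rec = taxonomy_by_gene.get(g.gene_id)
        taxon = rec.rank(rank) if rec is not None else None
        taxon = taxon if taxon is not None else "unclassified"
        if values == "count":
            v = 1.0
        elif values == "rpkm":
            if rpkm_values is None:
                raise ValueError("values='rpkm' requires rpkm_values")
            v = rpkm_values[g.gene_id]
        else:
            raise ValueError(f"unknown values mode {values!r}")
        cells[(g.sample_id, taxon)] = cells.get((g.sample_id, taxon), 0.0) + v
    sample_ids = sorted(samples)
    taxa = sorted({t for (_s, t) in cells})
    mat = pd.DataFrame(0.0, index=sample_ids, columns=taxa)
    for (s, t), v in cells.items():
        mat.loc[s, t] = v
    zero = mat.sum(axis=1) == 0
    if zero.any():
        logger.warning("zero-total samples flagged: %s", list(mat.index[zero]))
    grouping = {s: samples[s].environment for s in sample_ids}
    return mat, grouping


def bray_curtis(
    matrix: pd.DataFrame, measure: str = "braycurtis", close: bool = True
) -> pd.DataFrame:
    """Symmetric dissimilarity matrix between samples.

    d(i,j) = sum_k |x_ik - x_jk| / sum_k (x_ik + x_jk) for Bray–Curtis.
    Rows are closed to proportions first when ``close`` is true (the
    default), which makes the result invariant to uniform row scaling.
    All-zero rows are an error naming the sample.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; use one of {MEASURES}")
    X = matrix.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("negative cells in composition matrix")
    totals = X.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"all-zero rows for samples {list(matrix.index[zero])}; exclude them first"
        )
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if close:
        X = X / totals[:, None]
    if measure == "jaccard":
        D = squareform(pdist(X > 0, metric="jaccard"))
    else:
        D = squareform(pdist(X, metric=measure))
    return pd.DataFrame(D, index=matrix.index, columns=matrix.index)


def _sum_squared_within(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    ss_w = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_w += sub.sum() / (2.0 * idx.size)
    return ss_w


def permanova_stat(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(pseudo-F, R2) for one labelling of a squared-dissimilarity matrix."""
    n = d2.shape[0]
    groups = np.unique(labels)
    a = groups.size
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _sum_squared_within(d2, labels, groups)
    ss_between = ss_total - ss_within
    if a < 2:
        raise ValueError("need >= 2 groups (degenerate one-group design)")
    if n - a <= 0 or ss_within <= 0:
        raise ValueError("pseudo-F undefined: no within-group degrees of freedom")
    F = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return F, r2


def permanova(
    dissimilarity: pd.DataFrame,
    grouping: Mapping[str, str] | Sequence[str],
    n_permutations: int = 999,
    seed: int = DEFAULT_SEED,
) -> PermanovaResult:
    """One-way PERMANOVA with a seeded label-permutation p-value.

    ``grouping`` maps sample id -> group (or gives labels in row order).
    Requires >= 2 groups and >= 99 permutations. The observed pseudo-F never
    depends on the permutation count, only the p-value's resolution does.
    """
    D = dissimilarity.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("dissimilarity must be a symmetric square matrix")
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    if isinstance(grouping, Mapping):
        labels = np.array([grouping[s] for s in dissimilarity.index])
    else:
        labels = np.asarray(list(grouping))
        if labels.size != D.shape[0]:
            raise ValueError("grouping length does not match matrix size")
    d2 = D ** 2
    F_obs, r2 = permanova_stat(d2, labels)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        F_perm, _ = permanova_stat(d2, perm)
        if F_perm >= F_obs:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_permutations)
    logger.info(
        "permanova: F=%.4f R2=%.4f p=%.4g (%d permutations, seed %d)",
        F_obs, r2, p, n_permutations, seed,
    )
    return PermanovaResult(
        pseudo_F=F_obs, R2=r2, p_value=p, n_permutations=n_permutations, seed=seed
    )
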