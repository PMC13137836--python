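"""Cross-sample interaction signatures: core sets, UPGMA and PCA.

A *core* interaction set is the intersection, over every sample of a group, of
class-qualified canonical interaction ids (e.g. EPIs and PPIs present in all
three samples). Scores for those ids across samples form the signature
matrix; samples are then related by average-linkage (UPGMA) clustering on
Euclidean distances and by PCA with samples as observations — the R idiom
``t() |> dist(method="euclidean") |> hclust(method="average")`` and
``t() |> prcomp()`` respectively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist

from .io import Interaction

__all__ = [
    "core_interactions",
    "build_matrix",
    "upgma",
    "pca",
    "Dendrogram",
    "PCAResult",
]


def core_interactions(
    per_sample: Mapping[str, Sequence[Interaction]],
    class_filter: Iterable[str] = ("EPI", "PPI"),
) -> set[str]:
    """Canonical ids whose interaction passes the class filter in *every* sample.

    An id present everywhere but class-disqualified in even one sample (say,
    a peak-negative other end in that sample) is excluded.
    """
    if len(per_sample) < 2:
        raise ValueError("core_interactions requires >= 2 samples")
    wanted = set(class_filter)
    per_sample_ids: list[set[str]] = []
    for sample, interactions in per_sample.items():
        ids = set()
        for it in interactions:
            if it.regulatory_class is None:
                raise ValueError(
                    f"sample {sample}: interactions must be classified first"
                )
            if it.regulatory_class in wanted:
                ids.add(it.id)
        per_sample_ids.append(ids)
    return set.intersection(*per_sample_ids)


def build_matrix(
    ids: Iterable[str],
    per_sample_scores: Mapping[str, Mapping[str, float]],
    missing_policy: str = "zero",
) -> pd.DataFrame:
    """Assemble an ids x samples score matrix.

    ``missing_policy='zero'`` treats an unobserved interaction as evidence of
    absence at the score threshold and fills 0; ``'drop'`` removes any row not
    observed in every sample (sensitivity analysis).
    """
    if missing_policy not in ("zero", "drop"):
        raise ValueError("missing_policy must be 'zero' or 'drop'")
    ids = list(ids)
    data = {
        sample: [scores.get(i, np.nan) for i in ids]
        for sample, scores in per_sample_scores.items()
    }
    mat = pd.DataFrame(data, index=pd.Index(ids, name="interaction_id"))
    if missing_policy == "zero":
        return mat.fillna(0.0)
    return mat.dropna(axis=0, how="any")


@dataclass
class Dendrogram:
    """UPGMA result: scipy linkage plus sample labels and a merge list."""

    linkage_matrix: np.ndarray
    labels: list[str]

    @property
    def merges(self) -> list[tuple[frozenset[str], frozenset[str], float]]:
        """Each merge as (member labels of cluster A, of cluster B, height)."""
        n = len(self.labels)
        members: dict[int, frozenset[str]] = {
            i: frozenset([lab]) for i, lab in enumerate(self.labels)
        }
        out = []
        for k, (a, b, height, _) in enumerate(self.linkage_matrix):
            ma, mb = members[int(a)], members[int(b)]
            out.append((ma, mb, float(height)))
            members[n + k] = ma | mb
        return out

    def to_newick(self) -> str:
        tree = to_tree(self.linkage_matrix)

        def rec(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            dl = node.dist - node.left.dist
            dr = node.dist - node.right.dist
            return f"({rec(node.left)}:{dl:g},{rec(node.right)}:{dr:g})"

        return rec(tree) + ";"

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "cluster_a": "|".join(sorted(a)),
                "cluster_b": "|".join(sorted(b)),
                "height": h,
            }
            for a, b, h in self.merges
        ]
        return pd.DataFrame(rows)


def upgma(matrix: pd.DataFrame) -> Dendrogram:
    """Average-linkage agglomeration on Euclidean distances between samples.

    Samples are the matrix *columns*; merge heights are average inter-cluster
    distances and are non-decreasing (UPGMA admits no inversions).
    """
    if matrix.shape[1] < 2:
        raise ValueError("upgma requires >= 2 samples")
    values = matrix.to_numpy(dtype=float).T
    if not np.isfinite(values).all():
        raise ValueError("upgma requires finite values (fill or drop missing first)")
    z = linkage(pdist(values, metric="euclidean"), method="average")
    return Dendrogram(linkage_matrix=z, labels=list(matrix.columns))


@dataclass
class PCAResult:
    coordinates: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # features x components

    def reconstruct_centered(self) -> np.ndarray:
        return self.coordinates.to_numpy() @ self.loadings.to_numpy().T


def pca(matrix: pd.DataFrame, center: bool = True, scale: bool = False) -> PCAResult:
    """SVD-based PCA with samples (matrix columns) as observations.

    Columns are centered (and optionally unit-scaled, off by default to match
    the prcomp defaults); component signs are canonicalized so the
    largest-magnitude loading of each component is positive, making outputs
    deterministic across SVD implementations.
    """
    if matrix.shape[1] < 2:
        raise ValueError("pca requires >= 2 samples")
    if matrix.shape[0] < 1:
        raise ValueError("pca requires >= 1 feature")
    x = matrix.to_numpy(dtype=float).T  # samples x features
    if center:
        x = x - x.mean(axis=0, keepdims=True)
    if scale:
        sd = x.std(axis=0, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # sign canonicalization: largest-|loading| per component positive
    for k in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    scores = u * s
    n = x.shape[0]
    var = s**2 / max(n - 1, 1)
    total = var.sum()
    ratio = var / total if total > 0 else np.zeros_like(var)
    comp_names = [f"PC{k + 1}" for k in range(len(s))]
    return PCAResult(
        coordinates=pd.DataFrame(scores, index=matrix.columns, columns=comp_names),
        explained_variance_ratio=ratio,
        loadings=pd.DataFrame(vt.T, index=matrix.index, columns=comp_names),
    )
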