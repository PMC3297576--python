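"""Expression-profile similarity and sample clustering.

Gene expression follows a Zipf-like heavy-tailed law, so raw RPKM values are
power-law normalized before computing Pearson correlations; the default
normalization is the log10 transform (a rank-based alternative is offered).
Only genes with RPKM above a threshold in *every* sample enter the
comparison, which also guarantees positivity for the log.  Samples are then
clustered agglomeratively with (1 - PCC) as the distance and complete
linkage, and the dendrogram can be exported as Newick.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform


def expressed_in_all_filter(matrix: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Keep genes with expression strictly above ``threshold`` in every sample."""
    keep = (matrix > threshold).all(axis=1)
    filtered = matrix.loc[keep]
    if filtered.empty:
        raise ValueError(
            f"no gene exceeds {threshold} in all samples; review the threshold"
        )
    return filtered


def powerlaw_normalize(values, method: str = "log10"):
    """Variance-stabilize heavy-tailed expression values.

    ``log10`` (default) requires strictly positive input; ``rank`` maps each
    sample's values to average ranks.
    """
    if method == "log10":
        arr = np.asarray(values, dtype=float)
        if np.any(arr <= 0):
            raise ValueError("log10 normalization requires strictly positive values")
        out = np.log10(arr)
        if isinstance(values, pd.DataFrame):
            return pd.DataFrame(out, index=values.index, columns=values.columns)
        return out
    if method == "rank":
        frame = pd.DataFrame(values)
        return frame.rank(axis=0, method="average")
    raise ValueError(f"unknown normalization method {method!r}")


def pcc(x, y) -> float:
    """Pearson correlation coefficient of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pcc expects two equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("pcc requires at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pcc undefined for a zero-variance vector")
    return float(np.corrcoef(x, y)[0, 1])


def pcc_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise sample-sample PCC (columns of ``matrix`` are samples)."""
    for col in matrix.columns:
        if np.std(matrix[col].to_numpy()) == 0:
            raise ValueError(f"sample {col} has zero variance")
    return matrix.corr(method="pearson")


def cluster_samples(
    matrix: pd.DataFrame,
    threshold: float = 1.0,
    normalization: str = "log10",
) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Filter, normalize, correlate, and cluster the samples of an RPKM matrix.

    Returns ``(linkage_matrix, pcc_matrix, labels)`` where the linkage uses
    (1 - PCC) distances and complete linkage.  Deterministic for a given
    column order.
    """
    if matrix.shape[1] < 3:
        raise ValueError("clustering requires at least 3 samples")
    filtered = expressed_in_all_filter(matrix, threshold)
    normalized = powerlaw_normalize(filtered, method=normalization)
    corr = pcc_matrix(normalized)
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    z = linkage(condensed, method="complete")
    return z, corr, list(matrix.columns)


def to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Render a SciPy linkage matrix as a Newick string with branch lengths."""
    tree = to_tree(z)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0) if parent_height is not None else 0.0
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        suffix = f":{length:.6g}" if parent_height is not None else ""
        return f"({left},{right}){suffix}"

    return render(tree, None) + ";"


def clades(z: np.ndarray, labels: list[str]) -> list[frozenset[str]]:
    """Leaf sets of every internal node of the dendrogram."""
    n = len(labels)
    members: dict[int, frozenset[str]] = {i: frozenset([labels[i]]) for i in range(n)}
    out: list[frozenset[str]] = []
    for i, (a, b, _dist, _count) in enumerate(z):
        merged = members[int(a)] | members[int(b)]
        members[n + i] = merged
        out.append(merged)
    return out


def forms_clade(z: np.ndarray, labels: list[str], subset) -> bool:
    """True when ``subset`` appears as an exact clade of the dendrogram."""
    target = frozenset(subset)
    return target in set(clades(z, labels))
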