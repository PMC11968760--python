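"""Alpha diversity, beta-diversity distances, and PCoA ordination.

Alpha indices follow the usual conventions: Chao1 on integer read counts
(singleton/doubleton logic needs counts, not proportions), Shannon with the
natural logarithm, Simpson as the Gini-Simpson index 1 - sum p^2 (higher =
more diverse).  Distances are computed with scipy; ordination wraps
scikit-bio's PCoA (Gower double-centering + eigendecomposition) and applies
two reporting conventions on top: negative eigenvalues are truncated (kept
in the report, excluded from coordinates and explained fractions) and each
axis is oriented so its largest-magnitude loading is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import distance as ssd
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa


def chao1(counts) -> float:
    """Chao1 richness from integer counts.

    S_obs + F1^2/(2 F2) when doubletons exist; the bias-corrected
    S_obs + F1(F1-1)/2 when F2 = 0.
    """
    c = np.asarray(counts)
    if np.any(c < 0) or not np.allclose(c, np.round(c)):
        raise ValueError("chao1 requires non-negative integer counts")
    c = np.round(c).astype(int)
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def _proportions(vec) -> np.ndarray:
    v = np.asarray(vec, dtype=float)
    if np.any(v < 0):
        raise ValueError("abundances must be non-negative")
    total = v.sum()
    if total <= 0:
        raise ValueError("abundance vector must have positive sum")
    p = v / total
    return p[p > 0]


def shannon(vec) -> float:
    """Shannon entropy -sum p ln p (natural log)."""
    p = _proportions(vec)
    return float(-(p * np.log(p)).sum())


def simpson(vec) -> float:
    """Gini-Simpson index 1 - sum p^2."""
    p = _proportions(vec)
    return float(1.0 - (p * p).sum())


def alpha_diversity_frame(counts: pd.DataFrame) -> pd.DataFrame:
    """Chao1/Shannon/Simpson per sample from a samples x taxa count table."""
    rows = {}
    for sid, row in counts.iterrows():
        v = row.values
        rows[sid] = {"chao1": chao1(v), "shannon": shannon(v), "simpson": simpson(v)}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample"
    return df


_METRICS = ("jaccard_binary", "bray_curtis", "euclidean")


def distance(values: pd.DataFrame, metric: str) -> DistanceMatrix:
    """Pairwise sample distances for one of the three study metrics.

    jaccard_binary works on presence/absence (1 - |A&B|/|A|B|; 0 when both
    empty); bray_curtis is sum|x-y| / sum(x+y); euclidean is the L2 norm.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    x = values.to_numpy(dtype=float)
    if metric == "jaccard_binary":
        d = ssd.pdist(x > 0, metric="jaccard")
    elif metric == "bray_curtis":
        d = ssd.pdist(x, metric="braycurtis")
    else:
        d = ssd.pdist(x, metric="euclidean")
    return DistanceMatrix(ssd.squareform(d), ids=[str(i) for i in values.index])


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame      # samples x retained axes (positive eigenvalues)
    eigenvalues: np.ndarray        # all eigenvalues, descending (negatives included)
    explained_fraction: np.ndarray  # per retained axis, over positive eigenvalues

    def reconstructed_distances(self) -> np.ndarray:
        return ssd.squareform(ssd.pdist(self.coordinates.to_numpy()))


def pcoa(dm: DistanceMatrix | np.ndarray, n_axes: int | None = None,
         sample_ids=None) -> PCoAResult:
    """Principal coordinates of a sample distance matrix.

    Negative eigenvalues (non-Euclidean input) are reported but excluded
    from the coordinates and from the explained-fraction denominator; axis
    signs are fixed by making each axis's largest-|.| loading positive.
    """
    if not isinstance(dm, DistanceMatrix):
        arr = np.asarray(dm, dtype=float)
        if (arr < 0).any():
            raise ValueError("distance matrix has negative entries")
        dm = DistanceMatrix(arr, ids=[str(i) for i in (sample_ids or range(len(arr)))])
    if (dm.data < 0).any():
        raise ValueError("distance matrix has negative entries")
    n = dm.shape[0]
    if n_axes is None:
        n_axes = n - 1
    if n_axes > n - 1:
        raise ValueError("n_axes must be <= n_samples - 1")

    res = _skbio_pcoa(dm, method="eigh", number_of_dimensions=0)
    eigvals = res.eigvals.to_numpy()
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    coords = res.samples.to_numpy()[:, order]

    tol = 1e-12 * max(1.0, float(np.abs(eigvals).max()))
    pos = eigvals > tol
    keep = min(n_axes, int(pos.sum()))
    coords = coords[:, :keep]
    # deterministic orientation
    for j in range(keep):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] *= -1
    explained = eigvals[:keep] / eigvals[pos].sum() if keep else np.array([])
    cols = [f"axis{j + 1}" for j in range(keep)]
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=cols),
        eigenvalues=eigvals,
        explained_fraction=np.asarray(explained),
    )


def write_distance_tsv(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")


def write_pcoa_tsv(result: PCoAResult, groups: pd.Series, path) -> None:
    out = result.coordinates.copy()
    out["group"] = groups.reindex(out.index.astype(groups.index.dtype)).values \
        if len(groups) else ""
    out.to_csv(path, sep="\t", index_label="sample")
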