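"""Cross-modality validation statistics and phenotype embedding.

Paired per-ROI measurements from two modalities (e.g. nuclei/mm² by
immunofluorescence vs by mass cytometry) are compared with the
nonparametric Spearman rank correlation: Pearson correlation of
average-ranked values, with a t-approximation p-value (n - 2 degrees of
freedom) or, for small n, the exact permutation p over all n! rank
orderings.

For visualizing T-cell phenotype structure, selected per-cell features
(marker intensities and vessel distance) are log10-transformed and
z-scored, then embedded in 2D. The embedding backend is a deterministic
diffusion map on the k-nearest-neighbor graph — any diffusion-geometry
embedding honoring the (k, determinism) contract can be swapped in via
the ``backend`` hook of :func:`run_embedding`.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SpearmanResult",
    "spearman",
    "EmbeddingConfig",
    "prepare_embedding_features",
    "run_embedding",
]

LOG_EPS_FRACTION = 1e-3
_EXACT_N_MAX = 9  # exact permutation p offered up to 9! = 362880 orderings
_EXACT_AUTO_MAX = 7  # picked automatically only while enumeration is instant


@dataclass
class SpearmanResult:
    r: float
    p: float
    n: int
    method: str  # "t-approximation" | "exact-permutation"
    undefined: bool = False


def _spearman_r(x: np.ndarray, y: np.ndarray) -> float:
    rx = sps.rankdata(x)  # average ranks for ties
    ry = sps.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(
    x,
    y,
    *,
    exact: bool | None = None,
) -> SpearmanResult:
    """Spearman rank correlation of paired measurements.

    ``exact=None`` picks the exact permutation p-value when n <= 7 and the
    t-approximation otherwise (exact stays available up to n = 9). A constant vector leaves the correlation
    undefined (rank variance zero); the result is flagged rather than
    raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D vectors")
    n = x.size
    if n < 3:
        raise ValueError("Spearman correlation needs n >= 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return SpearmanResult(math.nan, math.nan, n, "undefined", undefined=True)

    r = _spearman_r(x, y)
    if exact is None:
        exact = n <= _EXACT_AUTO_MAX
    if exact:
        if n > _EXACT_N_MAX:
            raise ValueError(f"exact permutation p limited to n <= {_EXACT_N_MAX}")
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        rx = (rx - rx.mean()) / rx.std()
        count = 0
        total = 0
        tol = 1e-12
        for perm in itertools.permutations(ry):
            rp = np.asarray(perm)
            r_perm = float(np.mean(rx * (rp - rp.mean()) / rp.std()))
            if abs(r_perm) >= abs(r) - tol:
                count += 1
            total += 1
        return SpearmanResult(r, count / total, n, "exact-permutation")
    # t approximation with n - 2 degrees of freedom
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return SpearmanResult(r, p, n, "t-approximation")


def correlation_report(pairs: dict[str, tuple[np.ndarray, np.ndarray]]) -> pd.DataFrame:
    """(n, r, p) per compared quantity, as a tidy table."""
    rows = []
    for name, (x, y) in pairs.items():
        res = spearman(x, y)
        rows.append({"quantity": name, "n": res.n, "r": res.r, "p": res.p,
                     "method": res.method})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# embedding


@dataclass
class EmbeddingConfig:
    """Feature selection and neighborhood size for the 2D embedding."""

    features: tuple[str, ...] = (
        "CD3", "CD4", "CD8a", "CD38", "CD45", "HLA", "Ki67", "NFAT1",
        "distance_to_vessel_um",
    )
    k: int = 100
    diffusion_time: int = 8

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")


def prepare_embedding_features(
    cells: pd.DataFrame,
    cfg: EmbeddingConfig | None = None,
    *,
    metadata_columns: tuple[str, ...] = ("cell_class", "lesion_stage"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """log10(x + eps) then per-column z-scoring of the selected features.

    Marker features are read from ``norm_<marker>`` columns; other feature
    names must exist verbatim (e.g. the vessel distance). eps is 1e-3 of
    each column's scale (its max), so zero intensities and zero distances
    are handled without clipping the ordering. Zero-variance columns are
    dropped with a warning. Metadata columns pass through untransformed.
    """
    cfg = cfg or EmbeddingConfig()
    if cells.empty:
        raise ValueError("cell selection is empty")
    out = {}
    for feat in cfg.features:
        col = f"norm_{feat}" if f"norm_{feat}" in cells.columns else feat
        if col not in cells.columns:
            raise KeyError(f"feature {feat!r} not found in cell table")
        x = cells[col].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"feature {feat!r} contains undefined values")
        scale = float(np.max(x))
        eps = LOG_EPS_FRACTION * (scale if scale > 0 else 1.0)
        z = np.log10(x + eps)
        sd = z.std()
        # constant columns leave only floating-point residue in the std
        if sd < 1e-10 * max(1.0, abs(float(z.mean()))):
            warnings.warn(f"feature {feat!r} has zero variance; dropped", stacklevel=2)
            continue
        out[feat] = (z - z.mean()) / sd
    if not out:
        raise ValueError("no usable features remain after variance filtering")
    features = pd.DataFrame(out, index=cells.index)
    meta = cells[[c for c in metadata_columns if c in cells.columns]].copy()
    return features, meta


def _diffusion_map(X: np.ndarray, k: int, t: int) -> np.ndarray:
    """Deterministic diffusion-map coordinates (2D) on a kNN Gaussian kernel."""
    from sklearn.neighbors import NearestNeighbors

    n = X.shape[0]
    nn = NearestNeighbors(n_neighbors=k).fit(X)
    dist, idx = nn.kneighbors(X)
    # adaptive bandwidth: distance to the (k//3)-th neighbor
    sigma = np.maximum(dist[:, max(1, k // 3)], 1e-12)
    W = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    W[rows, idx.ravel()] = np.exp(-((dist.ravel() / sigma[rows]) ** 2))
    W = 0.5 * (W + W.T)  # symmetric affinities
    d = W.sum(axis=1)
    d[d == 0] = 1.0
    D_inv_sqrt = 1.0 / np.sqrt(d)
    S = W * np.outer(D_inv_sqrt, D_inv_sqrt)
    vals, vecs = np.linalg.eigh(S)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    psi = vecs * D_inv_sqrt[:, None]  # right eigenvectors of the Markov matrix
    coords = psi[:, 1:3] * (vals[1:3] ** t)
    # deterministic sign: the largest-magnitude entry of each axis is positive
    for j in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    return coords


def run_embedding(
    features: pd.DataFrame,
    cfg: EmbeddingConfig | None = None,
    *,
    seed: int = 0,
    backend=None,
) -> pd.DataFrame:
    """Embed prepared features into 2D coordinates, one row per cell.

    Deterministic for a fixed seed (the default diffusion-map backend is
    fully deterministic and ignores the seed beyond recording it).
    ``backend(X, k, seed) -> (n, 2) array`` swaps in another embedding,
    e.g. a PHATE implementation. Raises when k >= n cells.
    """
    cfg = cfg or EmbeddingConfig()
    X = features.to_numpy(dtype=float)
    n = X.shape[0]
    if cfg.k >= n:
        raise ValueError(f"k = {cfg.k} must be smaller than the number of cells ({n})")
    if backend is not None:
        coords = np.asarray(backend(X, cfg.k, seed))
    else:
        coords = _diffusion_map(X, cfg.k, cfg.diffusion_time)
    if coords.shape != (n, 2):
        raise ValueError(f"embedding backend returned shape {coords.shape}, expected ({n}, 2)")
    return pd.DataFrame(
        {"embed_1": coords[:, 0], "embed_2": coords[:, 1]}, index=features.index
    )
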