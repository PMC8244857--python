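"""PCA embedding of group mean profiles and cancer-normal distance ratios.

Cancer types and normal tissues are embedded jointly: each group's mean
profile (raw scale, log2-transformed by default) or specificity profile is
one observation and genes are the variables.  Genes are centered across
entities; no unit-variance scaling is applied by default.

For each cancer the *relative distance* is the Euclidean distance to its
paired normal tissue in the first ``dims`` components, divided by the
average distance from the cancer to every other entity.  A value of 1 means
the pair is no closer than a random entity; values below 1 mean the pair is
drawn together.  The *distance ratio* divides the specificity-space relative
distance by the raw-space one: ratios below 1 quantify how much the
specificity transform reveals the cancer-tissue coupling that raw mean
expression hides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .containers import MeanProfiles, ValidationError


class DegenerateError(ValidationError):
    """Raised when an embedding or distance is undefined (zero variance)."""


@dataclass
class Embedding:
    """PC coordinates of cancer/normal entities.

    ``coordinates`` is entities x components (columns ``PC1``, ``PC2``, ...),
    ``classes`` maps entity -> class, ``variances`` holds per-component
    variance (non-increasing).
    """

    coordinates: pd.DataFrame
    classes: pd.Series
    variances: np.ndarray

    def n_nonzero(self, tol: float = 1e-10) -> int:
        if len(self.variances) == 0:
            return 0
        return int(np.sum(self.variances > tol * self.variances[0]))


def fit_pca(
    matrix: pd.DataFrame,
    classes: pd.Series,
    log_transform: bool = False,
    scale: bool = False,
) -> Embedding:
    """PCA with entities (groups) as observations and genes as variables.

    Parameters
    ----------
    matrix
        Genes x entities values (mean profiles or specificity values).
    classes
        Entity -> ``"cancer"`` / ``"normal"``.
    log_transform
        Apply log2 before PCA (use for raw FPKM+1 means; specificity values
        are already log-scale).
    scale
        Also scale genes to unit variance (off by default).
    """
    X = matrix.to_numpy(dtype=float).T  # entities x genes
    if X.shape[0] < 3:
        raise ValidationError("PCA needs at least 3 entities")
    if np.isnan(X).any():
        raise ValidationError("missing values in PCA input")
    if log_transform:
        X = np.log2(X)
    if scale:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = X / sd
    if np.allclose(X, X[0], atol=1e-12):
        raise DegenerateError("constant matrix: PCA variance is zero")
    n_comp = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    coords = pd.DataFrame(
        scores, index=matrix.columns, columns=[f"PC{i+1}" for i in range(n_comp)]
    )
    return Embedding(coords, classes.reindex(matrix.columns), pca.explained_variance_)


def embed_means(means: MeanProfiles, log_transform: bool = True, scale: bool = False) -> Embedding:
    """Embed a combined cancer+normal mean-profile matrix (log2 by default)."""
    return fit_pca(means.values, means.classes, log_transform=log_transform, scale=scale)


def embed_specificity(spec: pd.DataFrame, classes: pd.Series, scale: bool = False) -> Embedding:
    """Embed a combined specificity matrix (already log-scale; used as-is)."""
    return fit_pca(spec, classes, log_transform=False, scale=scale)


def _resolve_dims(emb: Embedding, dims: int | str) -> int:
    if dims == "all-nonzero":
        return emb.n_nonzero()
    d = int(dims)
    if d < 1 or d > emb.coordinates.shape[1]:
        raise ValidationError(f"dims must be in [1, {emb.coordinates.shape[1]}]")
    return d


def relative_distance(
    emb: Embedding,
    cancer: str,
    tissue: str,
    dims: int | str = 2,
    include_pair_in_average: bool = False,
) -> float:
    """Pair distance divided by the cancer's average distance to all others.

    The averaging set is every other entity -- all other cancers and normal
    tissues -- excluding the focal cancer and (by default) its paired
    tissue.
    """
    coords = emb.coordinates
    for entity in (cancer, tissue):
        if entity not in coords.index:
            raise KeyError(f"entity {entity!r} not in embedding")
    d = _resolve_dims(emb, dims)
    X = coords.iloc[:, :d]
    focal = X.loc[cancer].to_numpy()
    pair_dist = float(np.linalg.norm(focal - X.loc[tissue].to_numpy()))
    others = [e for e in coords.index if e != cancer]
    if not include_pair_in_average:
        others = [e for e in others if e != tissue]
    if not others:
        raise ValidationError("no other entities to average over")
    dists = np.linalg.norm(X.loc[others].to_numpy() - focal, axis=1)
    denom = float(dists.mean())
    if denom <= 0:
        raise DegenerateError("all entities coincident: relative distance undefined")
    return pair_dist / denom


def distance_ratio(raw_rd: float, spec_rd: float) -> float:
    """Specificity-space relative distance over raw-space relative distance."""
    if raw_rd < 0 or spec_rd < 0:
        raise ValidationError("relative distances must be non-negative")
    if raw_rd == 0:
        raise DegenerateError("raw relative distance is zero: ratio undefined")
    return spec_rd / raw_rd


def distance_report(
    raw_emb: Embedding,
    spec_emb: Embedding,
    pairing: dict[str, str],
    dims: int | str = 2,
    include_pair_in_average: bool = False,
) -> pd.DataFrame:
    """Per-cancer relative distances in raw and specificity space and their ratio.

    Columns: ``tissue``, ``relative_distance``, ``specific_relative_distance``,
    ``distance_ratio``, ``dims``; one row per cancer in ``pairing``.
    """
    if set(raw_emb.coordinates.index) != set(spec_emb.coordinates.index):
        raise ValidationError("raw and specificity embeddings have different entities")
    rows = []
    for cancer, tissue in pairing.items():
        if cancer not in raw_emb.coordinates.index or tissue not in raw_emb.coordinates.index:
            raise KeyError(f"pairing entity missing from embedding: {cancer!r}/{tissue!r}")
        raw_rd = relative_distance(raw_emb, cancer, tissue, dims, include_pair_in_average)
        spec_rd = relative_distance(spec_emb, cancer, tissue, dims, include_pair_in_average)
        rows.append(
            {
                "cancer": cancer,
                "tissue": tissue,
                "relative_distance": raw_rd,
                "specific_relative_distance": spec_rd,
                "distance_ratio": distance_ratio(raw_rd, spec_rd),
                "dims": dims if dims == "all-nonzero" else int(dims),
            }
        )
    return pd.DataFrame(rows).set_index("cancer")
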