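"""Gradient embedding, template construction, Procrustes alignment and
gradient distance.

The embedding is a PCA of the (column-centred) affinity matrix: ROI scores
on the leading components are the "gradients" — continuous axes ordering
ROIs by the similarity of their connectivity profiles. Per-subject
embeddings are aligned to a group template by orthogonal Procrustes
rotation (rotation/reflection only, no scaling) so that component values
are comparable across subjects; the Euclidean distance between two ROIs in
the plane of the primary two aligned gradients measures their segregation
within the functional hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.distance import squareform, pdist

from .connectome import Connectome, affinity_from_fc, mean_fc


@dataclass(frozen=True)
class GradientEmbedding:
    """ROI × k component scores with per-component variance fractions.

    ``variance_explained[k]`` is sigma_k^2 / sum(sigma^2) over all N-1
    possible components, so the reported fractions sum to <= 1.
    """

    scores: np.ndarray
    variance_explained: np.ndarray
    aligned: bool = False
    reference_id: str | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.scores)
        v = np.asarray(self.variance_explained)
        if s.ndim != 2:
            raise ValueError("scores must be N×k")
        if v.shape != (s.shape[1],):
            raise ValueError("variance_explained length must equal k")
        if np.any(np.diff(v) > 1e-12):
            raise ValueError("variance_explained must be nonincreasing")
        if self.aligned and self.reference_id is None:
            raise ValueError("aligned embeddings must carry a reference_id")

    @property
    def n_roi(self) -> int:
        return self.scores.shape[0]

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    def component(self, dim: int) -> np.ndarray:
        """1-based component accessor (dim=1 is Gradient-1)."""
        if not 1 <= dim <= self.k:
            raise ValueError(f"dim {dim} outside 1..{self.k}")
        return self.scores[:, dim - 1]


def _orient_components(scores: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: each component's largest-|value|
    entry is made positive (ties resolved by the first such entry)."""
    out = scores.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            out[:, j] = -col
    return out


def pca_embedding(aff: Connectome | np.ndarray, k: int = 10) -> GradientEmbedding:
    """PCA gradient embedding of an affinity matrix.

    The affinity matrix is column-centred and its rows projected onto the
    top-k right singular vectors; the variance fraction of component k is
    sigma_k^2 / sum(sigma^2). Signs follow the largest-|loading|-positive
    convention so unaligned embeddings are reproducible.
    """
    a = aff.values if isinstance(aff, Connectome) else np.asarray(aff, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("affinity must be square")
    if not np.allclose(a, a.T, atol=1e-8):
        raise ValueError("affinity must be symmetric")
    n = a.shape[0]
    if not 2 <= k <= n - 1:
        raise ValueError(f"k must be in 2..{n - 1}, got {k}")
    centred = a - a.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    total = float(np.sum(s**2))
    scores = centred @ vt[:k].T
    var = s[:k] ** 2 / total if total > 0 else np.zeros(k)
    return GradientEmbedding(_orient_components(scores), var)


def build_template(connectomes: list[Connectome], *, threshold_fraction: float = 0.10,
                   k: int = 10, mode: str = "row",
                   reference_id: str = "template") -> GradientEmbedding:
    """Group gradient template from the element-wise mean connectome.

    Mean raw-r connectome of a held-out reference cohort → z → threshold →
    affinity → PCA. The result carries ``reference_id`` and is the target
    of all Procrustes alignments; build it from subjects disjoint from the
    analysis groups.
    """
    avg = mean_fc(connectomes)
    emb = pca_embedding(affinity_from_fc(avg, threshold_fraction, mode=mode), k=k)
    return replace(emb, reference_id=reference_id)


def procrustes_align(e: GradientEmbedding, template: GradientEmbedding
                     ) -> tuple[GradientEmbedding, float]:
    """Align an embedding to a template by orthogonal Procrustes.

    Finds the orthogonal Q (rotation or reflection; no scaling, no extra
    translation) minimising ||e.scores @ Q - template.scores||_F and
    returns (aligned embedding, Frobenius residual).
    """
    if e.scores.shape != template.scores.shape:
        raise ValueError(
            f"shape mismatch: embedding {e.scores.shape} vs template {template.scores.shape}"
        )
    q, _ = orthogonal_procrustes(e.scores, template.scores)
    aligned = e.scores @ q
    residual = float(np.linalg.norm(aligned - template.scores))
    ref = template.reference_id or "template"
    return (
        GradientEmbedding(aligned, e.variance_explained, aligned=True, reference_id=ref),
        residual,
    )


def gradient_distance(e: GradientEmbedding, dims: tuple[int, int] = (1, 2)) -> np.ndarray:
    """Euclidean inter-ROI distance in the plane of two aligned gradients.

    d_ij = sqrt((G_a(i)-G_a(j))^2 + (G_b(i)-G_b(j))^2) for dims (a, b).
    Requires an aligned embedding: distances are only comparable across
    subjects after alignment to a common template.
    """
    if not e.aligned:
        raise ValueError("gradient_distance requires a template-aligned embedding")
    pts = np.column_stack([e.component(d) for d in dims])
    return squareform(pdist(pts, metric="euclidean"))
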