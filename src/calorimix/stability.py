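"""Passage-to-passage stability and resilience of growth kinetics.

Reproducibility of heat-flow curves across serial passages is judged in a
PCA score space: each ampoule (replicate x passage) is one row of a matrix
over a common time grid, PCA is run on centered and unit-variance-scaled
columns, and passages are called stable once consecutive passage centroids
stop moving relative to the within-passage replicate dispersion.

Resilience of a perturbed community (one strain under-inoculated 100-fold)
is assessed by projecting its passages into the *reference* PCA space and
finding the first passage whose centroid falls within the reference
stable-region tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from calorimix.calorimetry import HeatFlowSeries, resample_to_grid

__all__ = [
    "PassageMatrix",
    "PCAResult",
    "StabilityReport",
    "ResilienceReport",
    "assemble_passage_matrix",
    "pca_scores",
    "project_scores",
    "detect_stable_passage",
    "assess_resilience",
    "composition_recovery",
]


@dataclass
class PassageMatrix:
    """Heat-flow rows (one per ampoule) over a common time grid."""

    values: np.ndarray  # (n_ampoules, n_times)
    passages: np.ndarray  # (n_ampoules,) 1-based
    replicates: list[str]
    grid: np.ndarray

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[0] != len(self.replicates):
            raise ValueError("row labels and matrix shape disagree")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("passage matrix contains non-finite values")


@dataclass
class PCAResult:
    scores: np.ndarray
    loadings: np.ndarray  # (n_components, n_kept_columns)
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    scale: np.ndarray | None
    kept_columns: np.ndarray
    no_variance: bool = False


@dataclass
class StabilityReport:
    """Outcome of the stable-passage search."""

    passages_to_stability: int | None
    reached: bool
    centroids: dict[int, np.ndarray]
    d_w: float
    k: float
    stable_centroid: np.ndarray | None = None
    shifts: dict[tuple[int, int], float] = field(default_factory=dict)


@dataclass
class ResilienceReport:
    recovery_passage: int | None
    recovered: bool
    distances: dict[int, float]
    threshold: float


def assemble_passage_matrix(series_list: list[HeatFlowSeries], grid) -> PassageMatrix:
    """Resample series to a common grid and stack rows ordered by (passage, replicate)."""
    grid = np.asarray(grid, dtype=float)
    resampled = []
    for s in series_list:
        try:
            r = resample_to_grid(s, grid)
        except ValueError as exc:
            raise ValueError(
                f"series (passage {s.passage}, replicate {s.replicate!r}, "
                f"condition {s.condition!r}) cannot be resampled: {exc}"
            ) from exc
        resampled.append(r)
    resampled.sort(key=lambda s: (s.passage, s.replicate))
    return PassageMatrix(
        values=np.vstack([s.power for s in resampled]),
        passages=np.array([s.passage for s in resampled]),
        replicates=[s.replicate for s in resampled],
        grid=grid,
    )


def pca_scores(
    matrix: PassageMatrix | np.ndarray,
    center: bool = True,
    scale: bool = True,
    n_components: int | None = None,
) -> PCAResult:
    """PCA by SVD of the centered (and scaled) data matrix.

    Zero-variance columns are dropped before unit-variance scaling (scaling
    is undefined there).  The sign of each component is fixed so its
    largest-magnitude loading is positive.  A matrix with no variance at all
    is flagged rather than an error: scores are all zero.
    """
    X = matrix.values if isinstance(matrix, PassageMatrix) else np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA needs a 2-D matrix with at least 2 rows")
    n, m = X.shape
    mean = X.mean(axis=0) if center else np.zeros(m)
    Xc = X - mean
    sd = Xc.std(axis=0, ddof=1)
    kept = np.where(sd > 1e-12)[0]
    if kept.size == 0:
        k = n_components or 1
        return PCAResult(
            scores=np.zeros((n, k)),
            loadings=np.zeros((k, 0)),
            explained_variance_ratio=np.zeros(k),
            mean=mean,
            scale=None,
            kept_columns=kept,
            no_variance=True,
        )
    Xk = Xc[:, kept]
    scale_vec = sd[kept] if scale else None
    if scale:
        Xk = Xk / scale_vec
    u, s, vt = np.linalg.svd(Xk, full_matrices=False)
    # sign convention: largest-magnitude loading positive
    for i in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    k = n_components or s.size
    k = min(k, s.size)
    evr = s**2 / np.sum(s**2)
    return PCAResult(
        scores=u[:, :k] * s[:k],
        loadings=vt[:k],
        explained_variance_ratio=evr[:k],
        mean=mean,
        scale=scale_vec,
        kept_columns=kept,
        no_variance=False,
    )


def project_scores(pca: PCAResult, X: np.ndarray) -> np.ndarray:
    """Project new rows into an existing PCA space (reference loadings)."""
    X = np.asarray(X, dtype=float)
    if pca.no_variance:
        return np.zeros((X.shape[0], pca.scores.shape[1]))
    Xk = (X - pca.mean)[:, pca.kept_columns]
    if pca.scale is not None:
        Xk = Xk / pca.scale
    return Xk @ pca.loadings.T


def _centroids_and_dispersion(scores: np.ndarray, passages: np.ndarray, n_components: int = 2):
    pts = scores[:, :n_components]
    uniq = np.unique(passages)
    centroids = {int(p): pts[passages == p].mean(axis=0) for p in uniq}
    dists = []
    for p in uniq:
        grp = pts[passages == p]
        if grp.shape[0] >= 2:
            dists.extend(np.linalg.norm(grp - grp.mean(axis=0), axis=1))
    d_w = float(np.mean(dists)) if dists else 0.0
    return centroids, d_w


def detect_stable_passage(
    scores: np.ndarray,
    passages: np.ndarray,
    k: float = 1.5,
    n_components: int = 2,
) -> StabilityReport:
    """First passage after which consecutive-passage centroids stop moving.

    The within-passage dispersion ``d_w`` (pooled mean replicate-to-centroid
    distance in the first ``n_components`` PCs) sets the scale; stability is
    the smallest passage ``p`` such that every later consecutive centroid
    shift is at most ``k * d_w``.  If no passage qualifies the report is
    flagged not-reached rather than raising.
    """
    passages = np.asarray(passages)
    uniq = np.unique(passages)
    if uniq.size < 2:
        raise ValueError("need >= 2 passages to assess stability")
    for p in uniq:
        if np.sum(passages == p) < 2:
            raise ValueError(f"passage {int(p)} has < 2 replicates")
    centroids, d_w = _centroids_and_dispersion(scores, passages, n_components)
    shifts = {}
    for a, b in zip(uniq[:-1], uniq[1:]):
        shifts[(int(a), int(b))] = float(np.linalg.norm(centroids[int(a)] - centroids[int(b)]))
    threshold = k * d_w
    stable = None
    # walk back from the last pair: find the longest suffix of small shifts
    for a, b in reversed(list(shifts)):
        if shifts[(a, b)] <= threshold:
            stable = a
        else:
            break
    reached = stable is not None
    stable_centroid = None
    if reached:
        stable_pass = uniq[uniq >= stable]
        stable_centroid = np.mean([centroids[int(p)] for p in stable_pass], axis=0)
    return StabilityReport(
        passages_to_stability=int(stable) if reached else None,
        reached=reached,
        centroids=centroids,
        d_w=d_w,
        k=k,
        stable_centroid=stable_centroid,
        shifts=shifts,
    )


def assess_resilience(
    perturbed: PassageMatrix,
    reference_pca: PCAResult,
    reference_report: StabilityReport,
    k: float | None = None,
) -> ResilienceReport:
    """Recovery passage of a perturbed run relative to a stable reference.

    Perturbed rows are projected with the reference loadings; the recovery
    passage is the first whose centroid lies within ``k * d_w`` (reference
    dispersion) of the reference stable-region centroid.  Flagged
    not-recovered when no passage qualifies.
    """
    if not reference_report.reached:
        raise ValueError("reference run never reached stability; no target to recover to")
    k = reference_report.k if k is None else k
    threshold = k * reference_report.d_w
    scores = project_scores(reference_pca, perturbed.values)
    n_comp = reference_report.stable_centroid.shape[0]
    centroids, _ = _centroids_and_dispersion(scores, perturbed.passages, n_comp)
    distances = {
        p: float(np.linalg.norm(c - reference_report.stable_centroid)) for p, c in centroids.items()
    }
    recovery = next((p for p in sorted(distances) if distances[p] <= threshold), None)
    return ResilienceReport(
        recovery_passage=recovery,
        recovered=recovery is not None,
        distances=distances,
        threshold=threshold,
    )


def composition_recovery(
    perturbed_fractions: dict[int, dict[str, float]],
    reference_fractions: dict[str, float],
    tol: float = 0.05,
) -> int | None:
    """First passage whose composition is within ``tol`` (absolute, per strain)
    of the reference composition; None if never."""
    for p in sorted(perturbed_fractions):
        fr = perturbed_fractions[p]
        if all(abs(fr.get(s, 0.0) - f) <= tol for s, f in reference_fractions.items()):
            return p
    return None
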