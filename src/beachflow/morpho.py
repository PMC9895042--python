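"""Landmark geometric morphometrics and colour-luminance normalization.

Head-shape variation is captured by 2-D landmark configurations.  Size is the
centroid size (root summed squared distances of landmarks from their
barycentre); shape is extracted by Generalized Procrustes Analysis —
translation to a common centroid, scaling to unit centroid size (partial
Procrustes), and iterative least-squares rotation to the evolving mean.  For
bilaterally symmetric structures, the object-symmetry decomposition splits
each aligned configuration into a symmetric component (average of the
original and its reflected-relabelled copy) and an asymmetric remainder;
downstream analyses use the symmetric component, summarized by a covariance
PCA truncated at 95% cumulative variance.

Dorsal luminance values are calibrated per image by a linear map anchored on
two grey-standard reflectances (10.17% and 59.41%) and analysed on the log10
scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LandmarkSet", "ProcrustesResult", "centroid_size", "gpa",
    "symmetry_decompose", "shape_pca_select", "normalize_luminance",
    "GREY_ANCHORS",
]

GREY_ANCHORS = (10.17, 59.41)  # known reflectances of the two grey standards


@dataclass
class LandmarkSet:
    """Specimen x k x 2 landmark configurations with a symmetry pairing.

    ``pairs`` lists (left, right) landmark index pairs; ``midline`` the
    indices on the symmetry axis.  Every landmark appears at most once in
    the map."""

    coords: np.ndarray
    pairs: list = field(default_factory=list)
    midline: list = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError("coords must be (specimens, landmarks, 2)")
        used = [i for p in self.pairs for i in p] + list(self.midline)
        if len(used) != len(set(used)):
            raise ValueError("duplicated landmark index in the symmetry map")
        if used and max(used) >= self.coords.shape[1]:
            raise ValueError("symmetry map exceeds landmark count")

    @property
    def n_specimens(self):
        return self.coords.shape[0]

    @property
    def n_landmarks(self):
        return self.coords.shape[1]

    def relabel_reflected(self):
        """Reflect x -> -x and swap left/right labels (object symmetry)."""
        ref = self.coords.copy()
        ref[:, :, 0] *= -1.0
        perm = np.arange(self.n_landmarks)
        for l, r in self.pairs:
            perm[l], perm[r] = perm[r], perm[l]
        return ref[:, perm, :]


def centroid_size(config: np.ndarray) -> float:
    """Root summed squared landmark distances from the barycentre."""
    config = np.asarray(config, float)
    if config.ndim != 2 or len(config) < 1:
        raise ValueError("config must be (k, 2)")
    c = config - config.mean(axis=0)
    cs = float(np.sqrt((c ** 2).sum()))
    if cs == 0.0:
        warnings.warn("degenerate configuration: centroid size 0")
    return cs


def _optimal_rotation(X, Y):
    """Rotation R (no reflection) minimizing ||X R - Y||_F."""
    U, s, Vt = np.linalg.svd(X.T @ Y)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, d])
    return U @ D @ Vt


@dataclass
class ProcrustesResult:
    aligned: np.ndarray      # (n, k, 2), centroid 0, centroid size 1
    mean_shape: np.ndarray   # (k, 2)
    centroid_sizes: np.ndarray
    iterations: int
    converged: bool


def gpa(coords, tol: float = 1e-8, max_iter: int = 100) -> ProcrustesResult:
    """Generalized Procrustes superimposition of 2-D configurations.

    Center, scale to unit centroid size, then iterate optimal rotations
    towards the current mean (itself renormalized each round) until the mean
    moves less than ``tol``.
    """
    X = np.asarray(coords, float)
    if isinstance(coords, LandmarkSet):
        X = coords.coords
    if X.ndim != 3 or X.shape[0] < 2:
        raise ValueError("need >= 2 specimens")
    n = X.shape[0]
    sizes = np.array([centroid_size(X[i]) for i in range(n)])
    if (sizes == 0).any():
        raise ValueError("degenerate specimen (zero centroid size)")
    A = (X - X.mean(axis=1, keepdims=True)) / sizes[:, None, None]
    mean = A[0].copy()
    mean /= np.sqrt((mean ** 2).sum())
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(n):
            A[i] = A[i] @ _optimal_rotation(A[i], mean)
        new_mean = A.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        nrm = np.sqrt((new_mean ** 2).sum())
        if nrm == 0:
            raise ValueError("degenerate mean shape")
        new_mean /= nrm
        # the mean is defined up to rotation: remove the rotational drift
        # before measuring convergence
        new_mean = new_mean @ _optimal_rotation(new_mean, mean)
        delta = np.sqrt(((new_mean - mean) ** 2).sum())
        mean = new_mean
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"GPA did not converge in {max_iter} iterations")
    return ProcrustesResult(A, mean, sizes, it, converged)


def symmetry_decompose(landmarks: LandmarkSet, tol: float = 1e-10):
    """Object-symmetry decomposition of a bilaterally symmetric structure.

    The originals and their reflected-relabelled copies are superimposed in
    one joint GPA; the symmetric component of each specimen is the average of
    the two aligned copies, the asymmetric component half their difference.
    Returns (symmetric (n, k, 2), asymmetric (n, k, 2), joint ProcrustesResult).
    """
    if not landmarks.pairs and not landmarks.midline:
        raise ValueError("symmetry map required for object symmetry")
    orig = landmarks.coords
    refl = landmarks.relabel_reflected()
    n = landmarks.n_specimens
    joint = gpa(np.concatenate([orig, refl], axis=0), tol=1e-10)
    A = joint.aligned[:n]
    R = joint.aligned[n:]
    sym = 0.5 * (A + R)
    asym = 0.5 * (A - R)
    return sym, asym, joint


def shape_pca_select(configs: np.ndarray, var_threshold: float = 0.95):
    """Covariance PCA of shape coordinates with the 95% retention rule.

    ``configs`` is (n, k, 2); returns (scores (n, n_kept), eigenvalues (all
    positive ones), k_kept) where k_kept is the smallest count reaching the
    cumulative-variance threshold.
    """
    if not (0.0 < var_threshold <= 1.0):
        raise ValueError("var_threshold must be in (0, 1]")
    X = np.asarray(configs, float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need >= 2 specimens")
    flat = X.reshape(n, -1)
    flat = flat - flat.mean(axis=0)
    U, s, Vt = np.linalg.svd(flat, full_matrices=False)
    eig = s ** 2 / (n - 1)
    pos = eig > eig.max() * 1e-12 if eig.max() > 0 else eig > -1
    eig = eig[pos]
    scores_all = U[:, pos] * s[pos]
    cum = np.cumsum(eig) / eig.sum()
    k = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    return scores_all[:, :k], eig, k


def normalize_luminance(values, grey_measured, grey_known=GREY_ANCHORS):
    """Two-point grey-standard calibration of mean pixel values.

    A linear map fixed by the two grey anchors (measured pixel value ->
    known reflectance %) is applied elementwise; anchors must be increasing.
    """
    g1, g2 = grey_measured
    k1, k2 = grey_known
    if g2 <= g1:
        raise ValueError("grey anchors must be increasing (g2 > g1)")
    slope = (k2 - k1) / (g2 - g1)
    return k1 + slope * (np.asarray(values, float) - g1)
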