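"""Landmark-based geometric morphometrics.

TPS file I/O, generalized Procrustes superimposition (GPA), Burnaby
orthogonal projection to remove a nuisance shape direction (dorsoventral
arching of photographed fish), PCA of shape coordinates, and size correction
of shape scores.  The transformer classes follow scikit-learn conventions
(``fit``/``transform``, fitted attributes with a trailing underscore) and the
module-level functions are thin wrappers over them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "LandmarkConfig",
    "ProcrustesResult",
    "ShapeScores",
    "read_tps",
    "write_tps",
    "GeneralizedProcrustes",
    "generalized_procrustes",
    "estimate_arching_basis",
    "BurnabyProjector",
    "burnaby_project",
    "head_subset",
    "ShapePCA",
    "shape_pca",
    "size_correct",
    "HEAD_LANDMARK_INDICES",
]

#: landmarks 1, 2, 12, 13, 15, 16 (0-based indices) form the head analysis
HEAD_LANDMARK_INDICES = (0, 1, 11, 12, 14, 15)

#: midline landmarks used for the arching score: jaw tip (1), eye (14),
#: operculum (16), lateral-line end (8); the dorsal/ventral peduncle pair
#: (7, 9) contributes its midpoint.
_MIDLINE = (0, 13, 15, 7)
_PEDUNCLE_PAIR = (6, 8)


@dataclass
class LandmarkConfig:
    """One digitized specimen: ordered 2-D landmarks, optional image scale."""

    fish_id: str
    coords: np.ndarray  # (k, 2)
    scale: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(f"{self.fish_id}: coords must be (k, 2)")


# ---------------------------------------------------------------------------
# TPS I/O


def read_tps(path, invert_y: bool = True) -> list[LandmarkConfig]:
    """Parse a TPS landmark file (``LM=``, coordinate lines, ``ID=``, ``SCALE=``).

    Image coordinate systems have y pointing down; with ``invert_y`` (default)
    y is negated on read so shapes are right side up.  ``write_tps`` applies
    the inverse, so write-then-read is the identity.
    """
    configs: list[LandmarkConfig] = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    i, record = 0, 0
    while i < len(lines):
        line = lines[i]
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise ValueError(f"{path}: record {record}: expected LM=, got {line!r}")
        k = int(line.split("=", 1)[1])
        coords = np.empty((k, 2))
        i += 1
        for j in range(k):
            if i >= len(lines) or "=" in lines[i] or not lines[i]:
                raise ValueError(
                    f"{path}: record {record}: LM={k} but only {j} coordinate lines"
                )
            parts = lines[i].split()
            if len(parts) != 2:
                raise ValueError(f"{path}: record {record}: bad coordinate line {lines[i]!r}")
            coords[j] = float(parts[0]), float(parts[1])
            i += 1
        fish_id, scale = None, None
        while i < len(lines) and lines[i] and "=" in lines[i] and not lines[i].upper().startswith("LM="):
            key, val = lines[i].split("=", 1)
            if key.upper() == "ID":
                fish_id = val.strip()
            elif key.upper() == "SCALE":
                scale = float(val)
            i += 1
        if fish_id is None:
            fish_id = f"record_{record}"
            warnings.warn(f"{path}: record {record} has no ID=, using {fish_id!r}")
        if invert_y:
            coords[:, 1] = -coords[:, 1]
        configs.append(LandmarkConfig(fish_id, coords, scale))
        record += 1
    return configs


def write_tps(configs: list[LandmarkConfig], path, invert_y: bool = True) -> None:
    with open(path, "w") as fh:
        for c in configs:
            fh.write(f"LM={len(c.coords)}\n")
            y_sign = -1.0 if invert_y else 1.0
            for x, y in c.coords:
                fh.write(f"{x:.6f} {y_sign * y:.6f}\n")
            fh.write(f"ID={c.fish_id}\n")
            if c.scale is not None:
                fh.write(f"SCALE={c.scale:.6f}\n")


def configs_to_array(configs) -> tuple[list[str], np.ndarray]:
    """Stack a list of LandmarkConfig into ids and an (n, k, 2) array."""
    if isinstance(configs, np.ndarray):
        arr = np.asarray(configs, dtype=float)
        return [f"spec_{i}" for i in range(len(arr))], arr
    ids = [c.fish_id for c in configs]
    ks = {c.coords.shape[0] for c in configs}
    if len(ks) != 1:
        raise ValueError(f"configurations have differing landmark counts: {sorted(ks)}")
    return ids, np.stack([c.coords for c in configs])


# ---------------------------------------------------------------------------
# GPA


def _optimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation R (no reflection) minimizing ||a @ R - b||_F."""
    u, _, vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(u @ vt))
    return (u * np.array([1.0, d])) @ vt


def _canonical_orientation(consensus: np.ndarray) -> np.ndarray:
    """Rotation placing the consensus in a reproducible orientation.

    Principal axes of the consensus define the coordinate frame (major axis
    along x); the 180-degree ambiguity is resolved by the sign of the
    x-coordinate third moment.  Only proper rotations are used, so the output
    orientation is independent of how the inputs happened to be oriented.
    """
    m = consensus.T @ consensus
    w, v = np.linalg.eigh(m)
    R = v[:, ::-1]  # descending: major axis first
    if np.linalg.det(R) < 0:
        R[:, 1] = -R[:, 1]
    rotated = consensus @ R
    skew = np.sum(rotated[:, 0] ** 3)
    if skew < 0 or (skew == 0 and np.sum(rotated[:, 1] ** 3) < 0):
        R = -R  # 180-degree rotation (det stays +1)
    return R


@dataclass
class ProcrustesResult:
    ids: list[str]
    aligned: np.ndarray  # (n, 2k)
    centroid_sizes: np.ndarray
    consensus: np.ndarray  # (k, 2)
    n_iter: int
    final_change: float

    @property
    def aligned_configs(self) -> np.ndarray:
        return self.aligned.reshape(len(self.aligned), -1, 2)


class GeneralizedProcrustes(TransformerMixin, BaseEstimator):
    """Generalized Procrustes superimposition.

    Each configuration is translated to centroid origin and scaled to unit
    centroid size; configurations are then iteratively rotated (optimal
    rotation, reflections disallowed — all photographs show the left side) to
    the running consensus until the consensus change falls below ``tol``.

    Attributes (after ``fit``): ``consensus_`` (k, 2), ``aligned_`` (n, 2k),
    ``centroid_sizes_``, ``n_iter_``, ``final_change_``.
    """

    def __init__(self, tol: float = 1e-10, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    def _normalize(self, arr: np.ndarray, ids) -> tuple[np.ndarray, np.ndarray]:
        centered = arr - arr.mean(axis=1, keepdims=True)
        sizes = np.sqrt((centered**2).sum(axis=(1, 2)))
        bad = np.nonzero(sizes <= 0)[0]
        if bad.size:
            names = [ids[i] for i in bad]
            raise ValueError(f"degenerate configuration (all landmarks coincident): {names}")
        return centered / sizes[:, None, None], sizes

    def fit(self, X, y=None):
        ids, arr = configs_to_array(X)
        if len(arr) < 2:
            raise ValueError("GPA needs at least 2 configurations")
        shapes, sizes = self._normalize(arr, ids)
        consensus = shapes[0].copy()
        consensus /= np.linalg.norm(consensus)
        n_iter, change = 0, np.inf
        for n_iter in range(1, self.max_iter + 1):
            rotated = np.stack([s @ _optimal_rotation(s, consensus) for s in shapes])
            new = rotated.mean(axis=0)
            new /= np.linalg.norm(new)
            change = float(np.linalg.norm(new - consensus))
            consensus = new
            if change < self.tol:
                break
        consensus = consensus @ _canonical_orientation(consensus)
        aligned = np.stack([s @ _optimal_rotation(s, consensus) for s in shapes])
        self.ids_ = ids
        self.consensus_ = consensus
        self.aligned_ = aligned.reshape(len(aligned), -1)
        self.centroid_sizes_ = sizes
        self.n_iter_ = n_iter
        self.final_change_ = change
        return self

    def transform(self, X) -> np.ndarray:
        ids, arr = configs_to_array(X)
        shapes, _ = self._normalize(arr, ids)
        aligned = np.stack([s @ _optimal_rotation(s, self.consensus_) for s in shapes])
        return aligned.reshape(len(aligned), -1)

    def result_(self) -> ProcrustesResult:
        return ProcrustesResult(
            ids=self.ids_,
            aligned=self.aligned_,
            centroid_sizes=self.centroid_sizes_,
            consensus=self.consensus_,
            n_iter=self.n_iter_,
            final_change=self.final_change_,
        )


def generalized_procrustes(configs, tol: float = 1e-10, max_iter: int = 100) -> ProcrustesResult:
    return GeneralizedProcrustes(tol=tol, max_iter=max_iter).fit(configs).result_()


# ---------------------------------------------------------------------------
# arching removal (Burnaby)


def arching_scores(result: ProcrustesResult) -> np.ndarray:
    """Signed quadratic-bend coefficient of each fish's midline landmarks."""
    configs = result.aligned_configs
    mid = configs[:, list(_MIDLINE), :]
    ped_mid = configs[:, list(_PEDUNCLE_PAIR), :].mean(axis=1, keepdims=True)
    pts = np.concatenate([mid, ped_mid], axis=1)  # (n, 5, 2)
    scores = np.empty(len(configs))
    for i, p in enumerate(pts):
        design = np.column_stack([np.ones(len(p)), p[:, 0], p[:, 0] ** 2])
        coef, *_ = np.linalg.lstsq(design, p[:, 1], rcond=None)
        scores[i] = coef[2]
    return scores


def estimate_arching_basis(result: ProcrustesResult, basis: np.ndarray | None = None) -> np.ndarray:
    """Unit nuisance direction in shape space along which arching varies.

    Default: regress the aligned coordinates on the per-fish arching score
    and normalize the slope vector.  A user-supplied ``basis`` overrides the
    estimate and is returned normalized.
    """
    if basis is not None:
        basis = np.asarray(basis, dtype=float).ravel()
        nrm = np.linalg.norm(basis)
        if nrm == 0:
            raise ValueError("user-supplied basis has zero norm")
        return basis / nrm
    s = arching_scores(result)
    s = s - s.mean()
    var = float(s @ s)
    if var < 1e-18:
        raise ValueError(
            "arching score has zero variance; supply a nuisance basis explicitly"
        )
    X = result.aligned - result.aligned.mean(axis=0)
    slope = (s @ X) / var
    nrm = np.linalg.norm(slope)
    if nrm == 0:
        raise ValueError("estimated arching direction is null; supply a basis explicitly")
    return slope / nrm


def burnaby_project(X: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Project data onto the orthogonal complement of the nuisance basis F.

    Returns ``X (I - F (F'F)^-1 F')``; rank-deficient F raises.
    """
    X = np.asarray(X, dtype=float)
    F = np.asarray(F, dtype=float)
    if F.ndim == 1:
        F = F[:, None]
    if np.linalg.matrix_rank(F) < F.shape[1]:
        raise ValueError("nuisance basis F is rank deficient")
    P = F @ np.linalg.solve(F.T @ F, F.T)
    return X - X @ P


class BurnabyProjector(TransformerMixin, BaseEstimator):
    """Remove the arching nuisance direction from aligned shape coordinates.

    With ``basis=None`` the direction is estimated from the data in ``fit``
    (regression on the midline quadratic-bend score); otherwise the supplied
    basis is used.  ``explained_variance_change_`` reports, per leading PC,
    the change in explained-variance fraction caused by the projection — the
    published diagnostic for whether arching mattered.
    """

    def __init__(self, basis: np.ndarray | None = None, n_diagnostic_pcs: int = 1):
        self.basis = basis
        self.n_diagnostic_pcs = n_diagnostic_pcs

    def fit(self, X, y=None):
        if isinstance(X, ProcrustesResult):
            result = X
        else:
            raise TypeError("BurnabyProjector.fit expects a ProcrustesResult")
        self.basis_ = estimate_arching_basis(result, self.basis)
        before = ShapePCA().fit(result.aligned)
        after = ShapePCA().fit(self.transform(result.aligned))
        m = self.n_diagnostic_pcs
        self.explained_variance_change_ = (
            after.explained_variance_ratio_[:m] - before.explained_variance_ratio_[:m]
        )
        return self

    def transform(self, X) -> np.ndarray:
        if isinstance(X, ProcrustesResult):
            X = X.aligned
        return burnaby_project(X, self.basis_)


# ---------------------------------------------------------------------------
# subsets, PCA, size correction


def head_subset(configs):
    """Restrict 16-landmark configurations to the six head landmarks.

    Accepts a list of LandmarkConfig or an (n, 16, 2) array; 6-landmark input
    is returned unchanged (the subset is idempotent).
    """
    idx = list(HEAD_LANDMARK_INDICES)
    if isinstance(configs, np.ndarray):
        if configs.shape[1] == len(idx):
            return configs.copy()
        return configs[:, idx, :]
    out = []
    for c in configs:
        if len(c.coords) == len(idx):
            out.append(LandmarkConfig(c.fish_id, c.coords.copy(), c.scale))
        else:
            out.append(LandmarkConfig(c.fish_id, c.coords[idx], c.scale))
    return out


@dataclass
class ShapeScores:
    scores: np.ndarray  # (n, n_pc)
    explained_variance_ratio: np.ndarray
    components: np.ndarray  # (n_pc, 2k) rows are eigenvectors
    mean: np.ndarray
    analysis: str = "body"
    ids: list = field(default_factory=list)


class ShapePCA(TransformerMixin, BaseEstimator):
    """PCA of (projected) Procrustes coordinates via eigendecomposition.

    Sign convention: each component's largest-magnitude loading is positive,
    so scores are reproducible across runs and platforms.  ``transform``
    returns the component scores of centered data.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if len(X) < 3:
            raise ValueError("shape PCA needs at least 3 specimens")
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        cov = Xc.T @ Xc / (len(X) - 1)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = np.clip(w[order], 0.0, None), v[:, order]
        flip = np.sign(v[np.abs(v).argmax(axis=0), np.arange(v.shape[1])])
        flip[flip == 0] = 1.0
        v = v * flip
        m = self.n_components or v.shape[1]
        self.components_ = v[:, :m].T
        self.explained_variance_ = w[:m]
        total = w.sum()
        self.explained_variance_ratio_ = w[:m] / total if total > 0 else np.zeros(m)
        return self

    def transform(self, X) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) @ self.components_.T

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        return scores @ self.components_ + self.mean_


def shape_pca(X: np.ndarray, n_components: int | None = None, analysis: str = "body",
              ids: list | None = None) -> ShapeScores:
    pca = ShapePCA(n_components=n_components).fit(X)
    return ShapeScores(
        scores=pca.transform(X),
        explained_variance_ratio=pca.explained_variance_ratio_,
        components=pca.components_,
        mean=pca.mean_,
        analysis=analysis,
        ids=list(ids) if ids is not None else [],
    )


def size_correct(scores: np.ndarray, tl: np.ndarray) -> np.ndarray:
    """Residuals of an OLS regression of a shape score on total length."""
    scores = np.asarray(scores, dtype=float).ravel()
    tl = np.asarray(tl, dtype=float).ravel()
    if scores.shape != tl.shape:
        raise ValueError("scores and TL must be paired")
    if len(scores) < 3:
        raise ValueError("size correction needs n >= 3")
    if np.ptp(tl) == 0:
        raise ValueError("total length is constant; size correction undefined")
    design = np.column_stack([np.ones_like(tl), tl])
    coef, *_ = np.linalg.lstsq(design, scores, rcond=None)
    return scores - design @ coef
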