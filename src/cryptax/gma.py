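"""Landmark-based geometric morphometrics.

TPS file I/O, generalized Procrustes analysis (GPA), principal component
and canonical variate analysis of the superimposed coordinates, and a
landmark-permutation test for the correlation between group covariance
matrices.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .errors import (
    InsufficientDataError,
    TPSFormatError,
    ValidationError,
)

logger = logging.getLogger(__name__)

N_LANDMARKS = 7


# ---------------------------------------------------------------------------
# containers and TPS I/O

@dataclass
class LandmarkDataset:
    """Per-specimen 2-D landmark configurations.

    ``coords`` has shape (n_specimens, k, 2) with landmarks in a fixed
    anatomical order shared by all specimens.
    """

    ids: list[str]
    species: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.ids)
        if len(self.species) != n or self.coords.shape[0] != n:
            raise ValidationError("ids, species and coords disagree in length")
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValidationError("coords must have shape (n, k, 2)")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    def partition(self) -> dict[str, str]:
        return dict(zip(self.ids, self.species))


def centroid_size(config: np.ndarray) -> float:
    """Square root of the summed squared distances to the centroid."""
    centered = config - config.mean(axis=0)
    return float(np.sqrt((centered**2).sum()))


def read_tps(path, expected_landmarks: int = N_LANDMARKS) -> LandmarkDataset:
    """Parse a TPS landmark file (``LM=``/``ID=`` records).

    ``IMAGE=``/``SCALE=``/``COMMENT=`` lines are ignored.  A record whose
    landmark count differs from ``expected_landmarks`` is rejected.
    Species labels are taken from an ``id|species`` convention in the ID
    field when present, else left empty.
    """
    ids: list[str] = []
    species: list[str] = []
    coords: list[np.ndarray] = []
    current: list[list[float]] | None = None
    current_n = 0
    current_id: str | None = None
    record_no = 0

    def flush() -> None:
        nonlocal current, current_id
        if current is None:
            return
        if len(current) != current_n:
            raise TPSFormatError(
                f"record {record_no} declares LM={current_n} but has {len(current)} rows"
            )
        rid = current_id if current_id is not None else f"record_{record_no}"
        if "|" in rid:
            plain, sp = rid.rsplit("|", 1)
        else:
            plain, sp = rid, ""
        ids.append(plain)
        species.append(sp)
        coords.append(np.array(current))
        current, current_id = None, None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM="):
                flush()
                record_no += 1
                try:
                    current_n = int(line[3:])
                except ValueError as exc:
                    raise TPSFormatError(f"line {lineno}: bad LM= count") from exc
                if current_n != expected_landmarks:
                    raise TPSFormatError(
                        f"record {record_no}: LM={current_n}, expected {expected_landmarks}"
                    )
                current = []
            elif upper.startswith("ID="):
                current_id = line[3:].strip()
            elif upper.startswith(("IMAGE=", "SCALE=", "COMMENT=")):
                continue
            else:
                if current is None:
                    raise TPSFormatError(f"line {lineno}: coordinates outside a record")
                parts = line.split()
                if len(parts) != 2:
                    raise TPSFormatError(f"line {lineno}: expected 'x y', got {line!r}")
                try:
                    current.append([float(parts[0]), float(parts[1])])
                except ValueError as exc:
                    raise TPSFormatError(f"line {lineno}: malformed number") from exc
    flush()
    if not ids:
        raise TPSFormatError("no landmark records found")
    return LandmarkDataset(ids, species, np.stack(coords))


def write_tps(dataset: LandmarkDataset, path) -> None:
    """Write a TPS file with ``id|species`` ID lines (round-trips read_tps)."""
    with open(path, "w") as fh:
        for sid, sp, config in zip(dataset.ids, dataset.species, dataset.coords):
            fh.write(f"LM={dataset.n_landmarks}\n")
            for x, y in config:
                fh.write(f"{x:.12g} {y:.12g}\n")
            label = f"{sid}|{sp}" if sp else sid
            fh.write(f"ID={label}\n")


# ---------------------------------------------------------------------------
# generalized Procrustes analysis

@dataclass
class ProcrustesFit:
    consensus: np.ndarray       # (k, 2), centered, unit centroid size
    aligned: np.ndarray         # (n, k, 2)
    centroid_sizes: np.ndarray  # (n,)
    iterations: int
    converged: bool
    objective_history: list[float] = field(default_factory=list)
    ids: list[str] = field(default_factory=list)
    species: list[str] = field(default_factory=list)

    def partition(self) -> dict[str, str]:
        return dict(zip(self.ids, self.species))


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation (det=+1) minimising ||source @ R - target||."""
    u, _, vt = np.linalg.svd(source.T @ target)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


def _canonical_orientation(consensus: np.ndarray) -> np.ndarray:
    """Deterministic rotation mapping the consensus to a canonical frame.

    Aligns the principal axis of the consensus with x and fixes the
    remaining 180-degree ambiguity so the landmark farthest from the
    centroid has positive x (ties broken towards positive y).
    """
    cov = consensus.T @ consensus
    theta = 0.5 * np.arctan2(2 * cov[0, 1], cov[0, 0] - cov[1, 1])
    c, s = np.cos(-theta), np.sin(-theta)
    rot = np.array([[c, -s], [s, c]])
    cand = consensus @ rot.T
    far = int(np.argmax((cand**2).sum(axis=1)))
    if cand[far, 0] < 0 or (cand[far, 0] == 0 and cand[far, 1] < 0):
        rot = -rot
    return rot


def gpa(
    dataset: LandmarkDataset, tol: float = 1e-10, max_iter: int = 100
) -> ProcrustesFit:
    """Generalized least-squares Procrustes superimposition.

    Each configuration is centered, scaled to unit centroid size and
    iteratively rotated (proper rotations only) onto the running
    consensus until the root-mean-square change of the consensus drops
    below ``tol``.  The output orientation is canonicalised so the fit is
    invariant to similarity transforms of the input.
    """
    if len(dataset) < 2:
        raise InsufficientDataError("GPA requires at least 2 configurations")
    n, k, _ = dataset.coords.shape
    sizes = np.empty(n)
    shapes = np.empty_like(dataset.coords)
    for idx, config in enumerate(dataset.coords):
        centered = config - config.mean(axis=0)
        size = np.sqrt((centered**2).sum())
        if size <= 0 or not np.isfinite(size):
            raise ValidationError(
                f"degenerate configuration {dataset.ids[idx]!r} (zero centroid size)"
            )
        sizes[idx] = size
        shapes[idx] = centered / size

    consensus = shapes[0].copy()
    history: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for idx in range(n):
            shapes[idx] = shapes[idx] @ _optimal_rotation(shapes[idx], consensus)
        mean = shapes.mean(axis=0)
        history.append(float(((shapes - mean) ** 2).sum()))
        new_consensus = mean - mean.mean(axis=0)
        new_consensus /= np.sqrt((new_consensus**2).sum())
        delta = np.sqrt(((new_consensus - consensus) ** 2).mean())
        consensus = new_consensus
        if delta < tol:
            converged = True
            break

    rot = _canonical_orientation(consensus)
    consensus = consensus @ rot.T
    shapes = shapes @ rot.T
    return ProcrustesFit(
        consensus=consensus,
        aligned=shapes,
        centroid_sizes=sizes,
        iterations=iterations,
        converged=converged,
        objective_history=history,
        ids=list(dataset.ids),
        species=list(dataset.species),
    )


# ---------------------------------------------------------------------------
# ordination of aligned coordinates

@dataclass
class LandmarkPCA:
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray      # (2k, n_components), columns are PCs
    percent_variance: np.ndarray  # over the nonzero spectrum, sums to 100
    scores: np.ndarray            # (n, n_components)
    degenerate: bool = False


def constraint_directions(consensus: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the 4 directions removed by superimposition.

    Translation in x and y, rescaling (radial direction at the consensus)
    and infinitesimal rotation about the consensus.
    """
    k = consensus.shape[0]
    t1 = np.zeros((k, 2))
    t1[:, 0] = 1.0
    t2 = np.zeros((k, 2))
    t2[:, 1] = 1.0
    radial = consensus.copy()
    rotational = np.column_stack([-consensus[:, 1], consensus[:, 0]])
    basis = np.stack([d.ravel() for d in (t1, t2, radial, rotational)])
    q, _ = np.linalg.qr(basis.T)
    return q.T  # (4, 2k)


def landmark_pca(fit: ProcrustesFit, zero_tol: float = 1e-12) -> LandmarkPCA:
    """PCA of the vectorised aligned coordinates in Procrustes tangent space.

    The translation, rotation and scale directions at the consensus are
    projected out first, so at most ``2k - 4`` eigenvalues are nonzero.
    A fit with (numerically) zero total variance is reported as
    degenerate.
    """
    n = fit.aligned.shape[0]
    if n < 3:
        raise InsufficientDataError("landmark PCA requires at least 3 specimens")
    X = fit.aligned.reshape(n, -1)
    Xc = X - X.mean(axis=0)
    constraints = constraint_directions(fit.consensus)
    Xc = Xc - (Xc @ constraints.T) @ constraints
    cov = (Xc.T @ Xc) / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    total = evals.sum()
    if total <= zero_tol:
        return LandmarkPCA(
            eigenvalues=evals,
            eigenvectors=evecs,
            percent_variance=np.zeros_like(evals),
            scores=np.zeros((n, evals.size)),
            degenerate=True,
        )
    max_rank = 2 * fit.aligned.shape[1] - 4  # similarity transforms remove 4 dof
    nonzero = evals > zero_tol * evals[0]
    nonzero[max_rank:] = False
    evals, evecs = evals[nonzero], evecs[:, nonzero]
    for col in range(evecs.shape[1]):  # sign convention
        peak = np.argmax(np.abs(evecs[:, col]))
        if evecs[peak, col] < 0:
            evecs[:, col] *= -1
    percent = 100.0 * evals / evals.sum()
    return LandmarkPCA(
        eigenvalues=evals,
        eigenvectors=evecs,
        percent_variance=percent,
        scores=Xc @ evecs,
    )


@dataclass
class CVAResult:
    eigenvalues: np.ndarray
    scores: np.ndarray           # (n, n_axes)
    groups: list[str]
    group_of: list[str]
    n_axes: int


def _group_indices(ids: list[str], partition: dict[str, str]) -> dict[str, np.ndarray]:
    missing = [i for i in ids if i not in partition]
    if missing:
        raise ValidationError(f"partition does not cover ids: {missing[:5]}")
    groups: dict[str, list[int]] = {}
    for idx, sid in enumerate(ids):
        groups.setdefault(partition[sid], []).append(idx)
    return {g: np.array(v) for g, v in groups.items()}


def cva(
    fit: ProcrustesFit,
    partition: dict[str, str] | None = None,
    n_keep: int | None = None,
) -> CVAResult:
    """Canonical variate analysis of the aligned coordinates.

    The rank-deficient Procrustes coordinates are first projected onto
    ``n_keep`` principal components (default: the rank of the pooled
    within-group covariance), then the between- vs pooled within-group
    generalized eigenproblem is solved, returning at most g-1 axes.
    """
    if partition is None:
        partition = fit.partition()
    groups = _group_indices(fit.ids, partition)
    if len(groups) < 2:
        raise ValidationError("CVA requires at least 2 groups")
    for g, idx in groups.items():
        if idx.size < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 specimens")
    n = fit.aligned.shape[0]
    X = fit.aligned.reshape(n, -1)
    Xc = X - X.mean(axis=0)
    within = np.vstack([Xc[idx] - Xc[idx].mean(axis=0) for idx in groups.values()])
    rank_w = np.linalg.matrix_rank(within, tol=1e-10)
    if n_keep is None:
        n_keep = int(rank_w)
    if n_keep < 1:
        raise InsufficientDataError("pooled within-group covariance has rank 0")
    evals, evecs = np.linalg.eigh((Xc.T @ Xc) / (n - 1))
    order = np.argsort(evals)[::-1][:n_keep]
    T = Xc @ evecs[:, order]
    g = len(groups)
    W = np.zeros((n_keep, n_keep))
    B = np.zeros((n_keep, n_keep))
    grand = T.mean(axis=0)
    for idx in groups.values():
        mu = T[idx].mean(axis=0)
        dev = T[idx] - mu
        W += dev.T @ dev
        B += idx.size * np.outer(mu - grand, mu - grand)
    W /= n - g
    B /= g - 1
    vals, vecs = linalg.eigh(B, W)
    order = np.argsort(vals)[::-1]
    n_axes = min(g - 1, n_keep)
    vals, vecs = vals[order][:n_axes], vecs[:, order][:, :n_axes]
    scores = T @ vecs
    return CVAResult(
        eigenvalues=np.clip(vals, 0.0, None),
        scores=scores,
        groups=list(groups),
        group_of=[partition[i] for i in fit.ids],
        n_axes=n_axes,
    )


# ---------------------------------------------------------------------------
# covariance-matrix correlation permutation test

@dataclass
class MatrixCorrelationResult:
    group_a: str
    group_b: str
    correlation: float
    p_value: float
    n_perm: int


def _offblock_lower_indices(k: int) -> tuple[np.ndarray, np.ndarray]:
    """Lower-triangle indices of a 2k x 2k matrix, excluding the per-landmark
    2x2 diagonal blocks (and the diagonal itself)."""
    rows, cols = np.tril_indices(2 * k, k=-1)
    keep = (rows // 2) != (cols // 2)
    return rows[keep], cols[keep]


def _block_permuted(cov: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Apply a landmark permutation to rows and columns of a 2k x 2k matrix."""
    idx = np.empty(cov.shape[0], dtype=int)
    idx[0::2] = 2 * perm
    idx[1::2] = 2 * perm + 1
    return cov[np.ix_(idx, idx)]


def covmat_correlation_test(
    fit: ProcrustesFit,
    partition: dict[str, str] | None = None,
    n_perm: int = 10000,
    seed: int = 0,
) -> list[MatrixCorrelationResult]:
    """Permutation test for the correlation of group covariance structures.

    For each pair of groups, the Pearson correlation between the lower
    triangles of the two covariance matrices of aligned coordinates is
    computed, keeping between-landmark blocks and excluding the
    within-landmark diagonal blocks.  The null distribution permutes
    landmark labels (identity excluded);
    ``p = (1 + #{perm >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 99:
        raise ValidationError("n_perm < 99 gives too coarse a p-value resolution")
    if partition is None:
        partition = fit.partition()
    groups = _group_indices(fit.ids, partition)
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    for g, idx in groups.items():
        if idx.size < 3:
            raise ValidationError(f"group {g!r} has fewer than 3 specimens")
    n, k, _ = fit.aligned.shape
    X = fit.aligned.reshape(n, -1)
    covs = {}
    for g, idx in groups.items():
        dev = X[idx] - X[idx].mean(axis=0)
        covs[g] = (dev.T @ dev) / (idx.size - 1)
    rows, cols = _offblock_lower_indices(k)
    rng = np.random.default_rng(seed)
    results = []
    for ga, gb in itertools.combinations(groups, 2):
        results.append(_one_matrix_test(covs[ga], covs[gb], ga, gb, rows, cols, k, n_perm, rng))
    return results


def matrix_correlation(cov_a: np.ndarray, cov_b: np.ndarray, k: int) -> float:
    """Pearson correlation of off-block lower-triangle covariance entries."""
    rows, cols = _offblock_lower_indices(k)
    return float(np.corrcoef(cov_a[rows, cols], cov_b[rows, cols])[0, 1])


def _one_matrix_test(
    cov_a: np.ndarray,
    cov_b: np.ndarray,
    ga: str,
    gb: str,
    rows: np.ndarray,
    cols: np.ndarray,
    k: int,
    n_perm: int,
    rng: np.random.Generator,
) -> MatrixCorrelationResult:
    va = cov_a[rows, cols]
    observed = float(np.corrcoef(va, cov_b[rows, cols])[0, 1])
    identity = np.arange(k)
    n_extreme = 0
    for _ in range(n_perm):
        perm = rng.permutation(k)
        while (perm == identity).all():
            perm = rng.permutation(k)
        vb = _block_permuted(cov_b, perm)[rows, cols]
        if np.corrcoef(va, vb)[0, 1] >= observed:
            n_extreme += 1
    p = (1 + n_extreme) / (n_perm + 1)
    return MatrixCorrelationResult(
        group_a=ga, group_b=gb, correlation=observed, p_value=p, n_perm=n_perm
    )
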