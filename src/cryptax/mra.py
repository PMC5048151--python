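"""Multivariate ratio analysis of linear measurements.

Decomposes log-measurements into an isometric size scalar and a zero-sum
shape vector, runs shape PCA, builds PCA and allometry ratio spectra
with bootstrap confidence intervals, and searches all character pairs
for the body ratio that best separates two groups (LDA ratio extractor).
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError, ValidationError
from .measurements import CHARACTERS, validate_measurement_table

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# shape space

@dataclass
class LogShapeSpace:
    """Isometric size and zero-sum log-shape coordinates per specimen."""

    ids: list[str]
    species: list[str]
    characters: tuple[str, ...]
    isosize: np.ndarray  # (n,)
    shape: np.ndarray    # (n, p), rows sum to zero

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_characters(self) -> int:
        return self.shape.shape[1]

    def log_values(self) -> np.ndarray:
        """Reconstruct the log-measurement matrix (isosize + shape)."""
        return self.isosize[:, None] + self.shape


def to_shape_space(table: pd.DataFrame) -> LogShapeSpace:
    """Split log-measurements into isometric size and shape.

    For specimen i with log-measurements y_i: ``isosize_i = mean(y_i)``
    and ``shape_i = y_i - isosize_i``.  The transform is lossless.
    """
    validate_measurement_table(table, require_positive=False)
    values = table[list(CHARACTERS)].to_numpy(dtype=float)
    bad = ~(values > 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DomainError(
            f"non-positive measurement: specimen {table['specimen_id'].iloc[i]!r}, "
            f"character {CHARACTERS[j]!r}"
        )
    y = np.log(values)
    isosize = y.mean(axis=1)
    return LogShapeSpace(
        ids=table["specimen_id"].astype(str).tolist(),
        species=table["species"].astype(str).tolist(),
        characters=CHARACTERS,
        isosize=isosize,
        shape=y - isosize[:, None],
    )


# ---------------------------------------------------------------------------
# shape PCA

@dataclass
class ShapePCA:
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray      # (p, n_components)
    percent_variance: np.ndarray  # sums to 100 over the nonzero spectrum
    scores: np.ndarray            # (n, n_components)


def _pca_of(shape: np.ndarray, zero_tol: float = 1e-12) -> ShapePCA:
    n = shape.shape[0]
    centered = shape - shape.mean(axis=0)
    cov = (centered.T @ centered) / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
    if evals[0] <= 0:
        raise InsufficientDataError("shape variance is zero; PCA undefined")
    nonzero = evals > zero_tol * evals[0]
    evals, evecs = evals[nonzero], evecs[:, nonzero]
    for col in range(evecs.shape[1]):  # largest-magnitude component positive
        peak = np.argmax(np.abs(evecs[:, col]))
        if evecs[peak, col] < 0:
            evecs[:, col] *= -1
    return ShapePCA(
        eigenvalues=evals,
        eigenvectors=evecs,
        percent_variance=100.0 * evals / evals.sum(),
        scores=centered @ evecs,
    )


def shape_pca(space: LogShapeSpace) -> ShapePCA:
    """PCA of the zero-sum shape vectors (pooled over species).

    At most p-1 eigenvalues are nonzero because shape vectors live in the
    zero-sum hyperplane; eigenvectors inherit (numerically) zero
    component sums.
    """
    if len(space) < 3:
        raise InsufficientDataError("shape PCA requires at least 3 specimens")
    if len(space) < space.n_characters + 1:
        logger.info(
            "shape PCA with n=%d < p+1=%d specimens: covariance is rank-deficient",
            len(space), space.n_characters + 1,
        )
    return _pca_of(space.shape)


# ---------------------------------------------------------------------------
# ratio spectra

@dataclass
class RatioSpectrum:
    """Character loadings on one shape axis, with bootstrap CIs.

    Characters at opposite ends of the sorted spectrum form the ratio
    most aligned with the axis; the loading of a ratio (i, j) is
    ``loading_i - loading_j``.
    """

    label: str
    characters: tuple[str, ...]
    loadings: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_boot: int

    def ordering(self) -> list[str]:
        """Characters sorted by loading, descending."""
        return [self.characters[i] for i in np.argsort(self.loadings)[::-1]]

    def extreme_pair(self) -> tuple[str, str]:
        """(argmax, argmin) characters: the spectrum-endpoint ratio."""
        return (
            self.characters[int(np.argmax(self.loadings))],
            self.characters[int(np.argmin(self.loadings))],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": self.label,
                "character": self.characters,
                "loading": self.loadings,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )


def _bootstrap_ci(
    point: np.ndarray,
    replicate_fn,
    n: int,
    n_boot: int,
    seed: int,
    ci: float = 95.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Percentile bootstrap over specimen resamples.

    ``replicate_fn(indices)`` returns a loading vector or None for a
    degenerate resample (skipped).  CIs are widened, if necessary, to
    contain the point estimate.
    """
    if n_boot < 2:
        raise ValidationError("n_boot must be at least 2")
    rng = np.random.default_rng(seed)
    reps = []
    attempts = 0
    while len(reps) < n_boot and attempts < 10 * n_boot:
        attempts += 1
        vec = replicate_fn(rng.integers(0, n, n))
        if vec is not None:
            reps.append(vec)
    if not reps:
        raise InsufficientDataError("all bootstrap resamples were degenerate")
    arr = np.asarray(reps)
    lo = np.percentile(arr, (100 - ci) / 2, axis=0)
    hi = np.percentile(arr, 100 - (100 - ci) / 2, axis=0)
    return np.minimum(lo, point), np.maximum(hi, point)


def pca_ratio_spectrum(
    space: LogShapeSpace, component: int = 1, n_boot: int = 1000, seed: int = 0
) -> RatioSpectrum:
    """Ratio spectrum of one shape principal component (1-based index).

    Bootstrap resamples specimens; each replicate eigenvector is matched
    by component index and sign-aligned (positive dot product) with the
    full-sample eigenvector before the percentile CIs are taken.
    """
    fit = shape_pca(space)
    if not 1 <= component <= fit.eigenvectors.shape[1]:
        raise ValidationError(
            f"component {component} out of range 1..{fit.eigenvectors.shape[1]}"
        )
    reference = fit.eigenvectors[:, component - 1]

    def replicate(idx: np.ndarray):
        sub = space.shape[idx]
        centered = sub - sub.mean(axis=0)
        cov = (centered.T @ centered) / max(len(idx) - 1, 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        if evals[order[0]] <= 1e-30 or component > np.sum(evals[order] > 1e-12 * evals[order[0]]):
            return None
        vec = evecs[:, order[component - 1]]
        return vec if vec @ reference >= 0 else -vec

    lo, hi = _bootstrap_ci(reference, replicate, len(space), n_boot, seed)
    return RatioSpectrum(
        label=f"PC{component}",
        characters=space.characters,
        loadings=reference.copy(),
        ci_lower=lo,
        ci_upper=hi,
        n_boot=n_boot,
    )


def allometry_ratio_spectrum(
    space: LogShapeSpace, n_boot: int = 1000, seed: int = 0
) -> RatioSpectrum:
    """Spectrum of per-character OLS slopes of shape on isometric size.

    Slopes sum to zero because the shape coordinates do.
    """
    iso = space.isosize
    if np.var(iso) <= 0:
        raise DomainError("isometric size is constant; allometric slopes undefined")

    def slopes(shape: np.ndarray, iso: np.ndarray):
        ic = iso - iso.mean()
        denom = ic @ ic
        if denom <= 0:
            return None
        return (ic @ (shape - shape.mean(axis=0))) / denom

    point = slopes(space.shape, iso)
    lo, hi = _bootstrap_ci(
        point, lambda idx: slopes(space.shape[idx], iso[idx]), len(space), n_boot, seed
    )
    return RatioSpectrum(
        label="allometry",
        characters=space.characters,
        loadings=point,
        ci_lower=lo,
        ci_upper=hi,
        n_boot=n_boot,
    )


# ---------------------------------------------------------------------------
# LDA ratio extractor

_ZERO_TOL = 1e-12


@dataclass
class RatioCandidate:
    numerator: str
    denominator: str
    standard_distance: float
    range_a: tuple[float, float]  # observed ratio min/max in group a
    range_b: tuple[float, float]


@dataclass
class LDARatioResult:
    group_a: str
    group_b: str
    best: RatioCandidate
    second: RatioCandidate
    delta: float
    standard_distance_lda: float
    separable: bool
    pair_distances: pd.DataFrame = field(repr=False, default=None)


def _standard_distance(ra: np.ndarray, rb: np.ndarray) -> float:
    """|mean difference| / pooled SD, with exact-degeneracy handling."""
    na, nb = ra.size, rb.size
    diff = abs(ra.mean() - rb.mean())
    pooled_var = ((na - 1) * ra.var(ddof=1) + (nb - 1) * rb.var(ddof=1)) / (na + nb - 2)
    pooled = np.sqrt(max(pooled_var, 0.0))
    if pooled < _ZERO_TOL:
        return 0.0 if diff < _ZERO_TOL else np.inf
    return float(diff / pooled)


def lda_ratio_extract(
    space: LogShapeSpace,
    partition: dict[str, str] | None = None,
    group_a: set[str] | str | None = None,
    group_b: set[str] | str | None = None,
) -> LDARatioResult:
    """Exhaustive search for the two best discriminating body ratios.

    Every unordered character pair (i, j) defines the log-ratio variable
    ``r = shape_i - shape_j = ln(x_i / x_j)``, scored by the standard
    distance between the two groups.  The second-best ratio shares no
    character with the best.  ``delta`` is the absolute cosine between
    the two-group LDA discriminant direction in full log-measurement
    space and the isometric direction (1, ..., 1)/sqrt(p): ~0 means the
    separation is carried by shape, ~1 by size.  Groups may be single
    species labels or pooled label sets.
    """
    if partition is None:
        partition = dict(zip(space.ids, space.species))
    labels = {sp for sp in partition.values()}
    if group_a is None or group_b is None:
        if len(labels) != 2:
            raise ValidationError("group_a/group_b required unless exactly 2 species")
        group_a, group_b = sorted(labels)
    set_a = {group_a} if isinstance(group_a, str) else set(group_a)
    set_b = {group_b} if isinstance(group_b, str) else set(group_b)
    if set_a & set_b:
        raise ValidationError("groups must be disjoint")
    member = np.array([partition[i] for i in space.ids])
    mask_a = np.isin(member, sorted(set_a))
    mask_b = np.isin(member, sorted(set_b))
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise InsufficientDataError("each group needs at least 3 specimens")

    p = space.n_characters
    shape_a, shape_b = space.shape[mask_a], space.shape[mask_b]
    rows = []
    for i, j in itertools.combinations(range(p), 2):
        ra = shape_a[:, i] - shape_a[:, j]
        rb = shape_b[:, i] - shape_b[:, j]
        rows.append(
            {
                "numerator": space.characters[i],
                "denominator": space.characters[j],
                "i": i,
                "j": j,
                "standard_distance": _standard_distance(ra, rb),
            }
        )
    pairs = pd.DataFrame(rows)

    def candidate(row) -> RatioCandidate:
        i, j = int(row["i"]), int(row["j"])
        ra = np.exp(shape_a[:, i] - shape_a[:, j])
        rb = np.exp(shape_b[:, i] - shape_b[:, j])
        return RatioCandidate(
            numerator=space.characters[i],
            denominator=space.characters[j],
            standard_distance=float(row["standard_distance"]),
            range_a=(float(ra.min()), float(ra.max())),
            range_b=(float(rb.min()), float(rb.max())),
        )

    best_row = pairs.loc[pairs["standard_distance"].idxmax()]
    disjoint = pairs[
        ~pairs["numerator"].isin([best_row["numerator"], best_row["denominator"]])
        & ~pairs["denominator"].isin([best_row["numerator"], best_row["denominator"]])
    ]
    second_row = disjoint.loc[disjoint["standard_distance"].idxmax()]

    # LDA direction in full log space, pooled within-group covariance
    y = space.log_values()
    ya, yb = y[mask_a], y[mask_b]
    na, nb = ya.shape[0], yb.shape[0]
    dev = np.vstack([ya - ya.mean(axis=0), yb - yb.mean(axis=0)])
    pooled = (dev.T @ dev) / (na + nb - 2)
    mean_diff = ya.mean(axis=0) - yb.mean(axis=0)
    evals, evecs = np.linalg.eigh(pooled)
    keep = evals > 1e-10 * max(evals[-1], _ZERO_TOL)
    if not keep.all():
        logger.warning(
            "pooled covariance is singular (rank %d/%d); using pseudo-inverse "
            "for the LDA axis", int(keep.sum()), p,
        )
    if keep.any():
        w = evecs[:, keep] @ ((evecs[:, keep].T @ mean_diff) / evals[keep])
    else:
        w = mean_diff.copy()
    norm_w = np.linalg.norm(w)
    separable = bool(norm_w > _ZERO_TOL and np.linalg.norm(mean_diff) > _ZERO_TOL)
    if separable:
        iso = np.ones(p) / np.sqrt(p)
        delta = float(abs(w @ iso) / norm_w)
        proj_a, proj_b = ya @ w, yb @ w
        d_lda = _standard_distance(proj_a, proj_b)
    else:
        logger.warning("groups are not separable; delta undefined")
        delta = float("nan")
        d_lda = 0.0

    name_a = group_a if isinstance(group_a, str) else "+".join(sorted(set_a))
    name_b = group_b if isinstance(group_b, str) else "+".join(sorted(set_b))
    return LDARatioResult(
        group_a=name_a,
        group_b=name_b,
        best=candidate(best_row),
        second=candidate(second_row),
        delta=delta,
        standard_distance_lda=d_lda,
        separable=separable,
        pair_distances=pairs.drop(columns=["i", "j"]),
    )
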