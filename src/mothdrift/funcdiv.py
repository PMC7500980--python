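"""Mixed-trait Gower dissimilarity, principal coordinates and functional dispersion.

Functional dispersion (FDis) of a community is the weighted mean distance of
its species to the community's weighted centroid in functional trait space:

    c    = sum_j a_j x_j / sum_j a_j
    z_j  = || x_j - c ||
    FDis = sum_j a_j z_j / sum_j a_j

with a_j the species weights (all 1 for incidence data) and x_j the species'
coordinates in a Euclidean embedding of the Gower dissimilarity matrix.
Because Gower dissimilarities over mixed traits are generally non-Euclidean,
the embedding step detects negative eigenvalues and applies a correction
(element-wise square root by default; Cailliez and Lingoes available) before
taking coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .traits import ORDINAL, QUANTITATIVE, FunctionalMatrix

logger = logging.getLogger(__name__)

#: axes with eigenvalue below this fraction of the largest one are dropped
EIG_REL_TOL = 1e-9


@dataclass
class DissimilarityMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("dissimilarity matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("dissimilarity matrix has nonzero diagonal")
        if np.any(v < 0):
            raise ValueError("negative dissimilarities")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DissimilarityMatrix":
        return cls(labels=list(df.index), values=df.to_numpy(dtype=float))


@dataclass
class Embedding:
    labels: list[str]
    coordinates: np.ndarray      # species x axes, axes ordered by eigenvalue
    eigenvalues: np.ndarray
    correction_applied: str = "none"
    dropped_columns: list[str] = field(default_factory=list)

    def coords_for(self, labels: list[str]) -> np.ndarray:
        idx = {l: i for i, l in enumerate(self.labels)}
        return self.coordinates[[idx[l] for l in labels]]


@dataclass
class FDisResult:
    value: float
    n_species_present: int
    weights_used: np.ndarray
    centroid: np.ndarray
    note: str = ""


def gower_matrix(
    fm: FunctionalMatrix,
    ranges: dict[str, float] | None = None,
) -> DissimilarityMatrix:
    """Gower dissimilarity over a typed mixed trait matrix.

    Per-trait contributions: quantitative |x_i - x_j| / range; ordinal the
    same after converting values to (average) ranks; binary and categorical
    simple mismatch (0 if equal, else 1). The pairwise dissimilarity is the
    weighted mean of contributions over traits observed in *both* species
    (pairwise deletion of missing values). Entries lie in [0, 1].

    Parameters
    ----------
    ranges
        Optional per-column ranges overriding the observed range of
        quantitative columns (useful for fixed trait scales).
    """
    values = fm.values
    n = len(values)
    if n < 2:
        raise ValueError("Gower dissimilarity needs at least 2 species")
    ranges = ranges or {}

    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for col in values.columns:
        kind = fm.column_types[col]
        w = fm.column_weights.get(col, 1.0)
        x = values[col]
        if kind in (QUANTITATIVE, ORDINAL):
            arr = pd.to_numeric(x).to_numpy(dtype=float)
            obs = ~np.isnan(arr)
            if kind == ORDINAL:
                # classic Gower: ordinal levels replaced by their ranks
                r = np.full(n, np.nan)
                if obs.any():
                    r[obs] = rankdata(arr[obs], method="average")
                arr = r
            rng = ranges.get(col)
            if rng is None:
                rng = np.nanmax(arr) - np.nanmin(arr) if obs.any() else 0.0
            if rng == 0 or not np.isfinite(rng):
                logger.warning("zero-range column %r dropped from Gower", col)
                continue
            diff = np.abs(arr[:, None] - arr[None, :]) / rng
            valid = obs[:, None] & obs[None, :]
        else:
            arr = x.to_numpy(dtype=object)
            obs = np.array([not _is_missing(v) for v in arr])
            eq = arr[:, None] == arr[None, :]
            diff = (~eq).astype(float)
            valid = obs[:, None] & obs[None, :]
        diff = np.where(valid, diff, 0.0)
        num += w * diff
        den += w * valid

    if np.any(den == 0):
        i, j = np.argwhere(den == 0)[0]
        raise ValueError(
            f"species pair ({values.index[i]!r}, {values.index[j]!r}) shares no observed trait"
        )
    d = num / den
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DissimilarityMatrix(labels=list(values.index), values=d)


def _is_missing(v) -> bool:
    if v is None:
        return True
    try:
        return bool(pd.isna(v))
    except (TypeError, ValueError):
        return False


def _double_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _eig_embed(d: np.ndarray, rel_tol: float) -> tuple[np.ndarray, np.ndarray, float]:
    b = _double_center(d)
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    lmax = max(eigval[0], 0.0)
    min_eig = eigval[-1]
    keep = eigval > rel_tol * lmax if lmax > 0 else np.zeros_like(eigval, dtype=bool)
    coords = eigvec[:, keep] * np.sqrt(eigval[keep])
    return coords, eigval[keep], min_eig


def _cailliez_constant(d: np.ndarray) -> float:
    """Smallest additive constant making d + c (off-diagonal) Euclidean."""
    n = d.shape[0]
    delta1 = _double_center(d)
    delta2 = -0.5 * (d - d.mean(axis=1, keepdims=True) - d.mean(axis=0, keepdims=True) + d.mean())
    upper = np.hstack([np.zeros((n, n)), 2 * delta1])
    lower = np.hstack([-np.eye(n), -4 * delta2])
    special = np.vstack([upper, lower])
    ev = np.linalg.eigvals(special)
    return float(np.max(ev.real))


def pcoa_embed(
    D: DissimilarityMatrix,
    correction: str = "sqrt",
    rel_tol: float = EIG_REL_TOL,
) -> Embedding:
    """Principal-coordinates embedding with negative-eigenvalue correction.

    The double-centred matrix -0.5 D^2 is eigendecomposed; axes with
    eigenvalue above ``rel_tol`` x the largest are retained. If the most
    negative eigenvalue exceeds the same tolerance in magnitude, the
    configured correction is applied and the matrix re-embedded:

    - ``sqrt``: element-wise square root of the dissimilarities (default);
    - ``cailliez``: additive constant on the dissimilarities;
    - ``lingoes``: additive constant on the squared dissimilarities;
    - ``none``: raise if the matrix is not embeddable.
    """
    if correction not in ("sqrt", "cailliez", "lingoes", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    d = D.values
    coords, eigval, min_eig = _eig_embed(d, rel_tol)
    lmax = eigval[0] if len(eigval) else 0.0
    applied = "none"
    if lmax > 0 and min_eig < -rel_tol * lmax * d.shape[0]:
        if correction == "none":
            raise ValueError(
                f"dissimilarity matrix not Euclidean-embeddable "
                f"(most negative eigenvalue {min_eig:.3g}) and correction disabled"
            )
        if correction == "sqrt":
            d2 = np.sqrt(d)
        elif correction == "lingoes":
            c = -min_eig
            d2 = np.sqrt(d ** 2 + 2 * c)
            np.fill_diagonal(d2, 0.0)
        else:  # cailliez
            c = _cailliez_constant(d)
            d2 = d + c
            np.fill_diagonal(d2, 0.0)
        coords, eigval, min_eig2 = _eig_embed(d2, rel_tol)
        applied = correction
        lmax2 = eigval[0] if len(eigval) else 0.0
        if lmax2 > 0 and min_eig2 < -1e-6 * lmax2 * d.shape[0]:
            raise ValueError(
                f"{correction} correction left a negative eigenvalue ({min_eig2:.3g})"
            )
    return Embedding(
        labels=list(D.labels),
        coordinates=coords,
        eigenvalues=eigval,
        correction_applied=applied,
    )


def fdis(embedding: Embedding, weights) -> FDisResult:
    """Functional dispersion: weighted mean distance to the weighted centroid.

    Parameters
    ----------
    embedding
        Species coordinates from :func:`pcoa_embed` (or any Euclidean
        coordinates with matching labels).
    weights
        Per-species non-negative weights a_j, aligned with
        ``embedding.labels`` (array-like) or indexed by species id (Series,
        dict). With incidence data, present species get weight 1 and absent
        species 0.
    """
    if isinstance(weights, pd.Series):
        a = weights.reindex(embedding.labels).fillna(0.0).to_numpy(dtype=float)
    elif isinstance(weights, dict):
        a = np.array([weights.get(l, 0.0) for l in embedding.labels], dtype=float)
    else:
        a = np.asarray(weights, dtype=float)
        if a.shape != (len(embedding.labels),):
            raise ValueError("weights length does not match embedding labels")
    if np.any(a < 0):
        raise ValueError("negative weights")
    total = a.sum()
    if total == 0:
        raise ValueError("all weights zero")

    present = a > 0
    n_present = int(present.sum())
    x = embedding.coordinates[present]
    ap = a[present]
    centroid = (ap[:, None] * x).sum(axis=0) / ap.sum()
    if n_present <= 1:
        return FDisResult(0.0, n_present, a, centroid, note="single species present")
    z = np.linalg.norm(x - centroid, axis=1)
    value = float((ap * z).sum() / ap.sum())
    return FDisResult(value, n_present, a, centroid)


def fdis_per_layer(embedding: Embedding, incidence: pd.DataFrame) -> pd.Series:
    """FDis of each time layer, weighting present species equally.

    The embedding is computed once for the full species pool; each layer's
    dispersion uses the coordinates of its present species only, as the
    incidence-weighted case of the general formula.
    """
    out = {}
    for layer in incidence.columns:
        out[layer] = fdis(embedding, incidence[layer].astype(float)).value
    return pd.Series(out, name="fdis")


def fdis_brute_oracle(
    D_or_fm,
    weights,
    correction: str = "sqrt",
) -> float:
    """Definitional FDis computed without any eigen-embedding (test oracle).

    For points embeddable from a Euclidean distance matrix, the squared
    distance of point j to the weighted centroid follows directly from the
    pairwise distances (Gower's centroid identity):

        z_j^2 = sum_k w_k d_jk^2 - (1/2) sum_k sum_l w_k w_l d_kl^2

    with w the weights normalized over present species. The same correction
    as the production path is applied to make the matrix Euclidean, but the
    centroid distances are then obtained purely from the corrected distances,
    independently of the eigendecomposition route.
    """
    if isinstance(D_or_fm, FunctionalMatrix):
        D = gower_matrix(D_or_fm)
    else:
        D = D_or_fm
    d = D.values.copy()

    _, _, min_eig = _eig_embed(d, EIG_REL_TOL)
    b = _double_center(d)
    lmax = float(np.max(np.linalg.eigvalsh(b)))
    if lmax > 0 and min_eig < -EIG_REL_TOL * lmax * d.shape[0]:
        if correction == "sqrt":
            d = np.sqrt(d)
        elif correction == "lingoes":
            c = -min_eig
            d = np.sqrt(d ** 2 + 2 * c)
            np.fill_diagonal(d, 0.0)
        elif correction == "cailliez":
            d = d + _cailliez_constant(d)
            np.fill_diagonal(d, 0.0)
        else:
            raise ValueError("matrix not embeddable and correction disabled")

    if isinstance(weights, pd.Series):
        a = weights.reindex(D.labels).fillna(0.0).to_numpy(dtype=float)
    else:
        a = np.asarray(weights, dtype=float)
    present = a > 0
    if present.sum() <= 1:
        return 0.0
    w = a[present] / a[present].sum()
    dp2 = d[np.ix_(present, present)] ** 2
    to_all = dp2 @ w
    mean_all = w @ dp2 @ w
    z2 = to_all - 0.5 * mean_all
    z = np.sqrt(np.clip(z2, 0.0, None))
    return float(w @ z)
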