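"""Sørensen dissimilarity, non-metric multidimensional scaling and vector fitting.

Compositional change between time layers is summarized by NMDS on Sørensen
dissimilarities (incidence-based), and the association of community
descriptors (log mean wingspan, mean total specialization, logit proportion
of open-habitat species) with the ordination is tested by least-squares
vector fitting with a permutation null, envfit-style.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS

from .funcdiv import DissimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass
class OrdinationResult:
    layer_labels: list[str]
    coordinates: np.ndarray      # layers x n_axes, centred at the origin
    stress: float                # Kruskal stress-1
    n_restarts: int
    converged: bool
    seed: int

    def to_frame(self) -> pd.DataFrame:
        cols = [f"nmds{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.layer_labels, columns=cols)


@dataclass
class VectorFit:
    variable_name: str
    direction_cosines: np.ndarray
    r_squared: float
    p_value: float
    n_permutations: int

    def to_dict(self) -> dict:
        return {
            "variable": self.variable_name,
            "direction": [float(v) for v in self.direction_cosines],
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
        }


def sorensen_dissimilarity(incidence: pd.DataFrame) -> DissimilarityMatrix:
    """Sørensen dissimilarity between time layers from binary incidence.

    For layers X and Y with a shared species, b unique to X and c unique to
    Y, similarity is 2a / (2a + b + c); dissimilarity is its complement
    (identical to the Dice dissimilarity on binary vectors).
    """
    if incidence.shape[1] < 2:
        raise ValueError("need at least two layers")
    x = (incidence.to_numpy() > 0).astype(bool).T  # layers x species
    empty = ~x.any(axis=1)
    if empty.any():
        bad = [incidence.columns[i] for i in np.where(empty)[0]]
        raise ValueError(f"layers with zero species must be dropped upstream: {bad}")
    d = squareform(pdist(x, metric="dice"))
    return DissimilarityMatrix(labels=list(incidence.columns), values=d)


def _stress1(d_obs: np.ndarray, d_fit: np.ndarray) -> float:
    """Kruskal stress-1 with disparities from isotonic regression of the
    fitted distances on the observed dissimilarities (ties pooled)."""
    disp = IsotonicRegression().fit_transform(d_obs, d_fit)
    denom = float((d_fit ** 2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d_fit - disp) ** 2).sum() / denom))


def nmds(
    D: DissimilarityMatrix,
    n_axes: int = 2,
    n_restarts: int = 50,
    seed: int = 0,
    max_iter: int = 500,
    eps: float = 1e-6,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1 (monotone regression).

    The best solution over ``n_restarts`` random starts is retained;
    coordinates are centred at the origin. Deterministic for a given seed.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mds = MDS(
            n_components=n_axes,
            metric=False,
            dissimilarity="precomputed",
            n_init=n_restarts,
            random_state=seed,
            max_iter=max_iter,
            eps=eps,
            normalized_stress=True,
        )
        coords = mds.fit_transform(D.values)
    coords = coords - coords.mean(axis=0, keepdims=True)
    d_fit = pdist(coords)
    stress = _stress1(squareform(D.values), d_fit)
    converged = mds.n_iter_ < max_iter
    if not converged:
        logger.warning("NMDS did not converge in %d iterations (stress %.4f)", max_iter, stress)
    return OrdinationResult(
        layer_labels=list(D.labels),
        coordinates=coords,
        stress=stress,
        n_restarts=n_restarts,
        converged=bool(converged),
        seed=seed,
    )


def permutation_vector_fit(
    ordination: OrdinationResult,
    variables: pd.DataFrame,
    n_permutations: int = 999,
    seed: int = 0,
) -> list[VectorFit]:
    """Fit descriptor vectors onto the ordination, with a permutation test.

    Each descriptor is projected onto the ordination axes by least squares;
    R^2 is the squared multiple correlation. The p-value counts permutations
    of the descriptor values across layers whose R^2 reaches the observed
    one, with the add-one correction: p = (#{R^2_perm >= R^2_obs} + 1) /
    (n_permutations + 1), hence p >= 1/(n_permutations + 1).
    """
    vars_df = variables.loc[list(ordination.layer_labels)]
    x = ordination.coordinates
    n = x.shape[0]
    xc = x - x.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(xc)
    rng = np.random.default_rng(seed)

    fits = []
    for name in vars_df.columns:
        y = vars_df[name].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            raise ValueError(f"constant descriptor {name!r} cannot be fitted")
        yc = y - y.mean()
        ss_tot = float(yc @ yc)
        beta = np.linalg.lstsq(xc, yc, rcond=None)[0]
        proj = q.T @ yc
        r2 = float(proj @ proj / ss_tot)

        perms = np.empty((n_permutations, n))
        for i in range(n_permutations):
            perms[i] = yc[rng.permutation(n)]
        pp = perms @ q                      # (n_perm, n_axes)
        r2_perm = (pp ** 2).sum(axis=1) / ss_tot
        p = float((np.sum(r2_perm >= r2 - 1e-12) + 1) / (n_permutations + 1))

        norm = np.linalg.norm(beta)
        direction = beta / norm if norm > 0 else beta
        fits.append(VectorFit(name, direction, r2, p, n_permutations))
    return fits
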