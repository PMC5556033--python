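"""Sammon mapping of whole simulations.

Each simulation is summarized by its per-position PB frequency signature; the
dissimilarity between two simulations is the normalized mean per-position ΔPB
(a scaled L1 metric in [0, 1]).  Sammon's nonlinear mapping then embeds the
simulations in 2D by minimizing

    E = (1 / Σ_{i<j} δ_ij) · Σ_{i<j} (δ_ij − d_ij)² / δ_ij

where δ are input dissimilarities and d embedded Euclidean distances.  The
inverse-δ weighting preserves small distances instead of letting outliers
dominate, which is why it suits run-to-run comparison: one point per
simulation, one barycentre per system.

The optimizer is Sammon's diagonal second-order update damped by a "magic
factor", guarded by step-halving so the stress never increases between
accepted iterations; initialization is classical metric scaling (exact for
distances that are Euclidean in 2D), with a seeded random fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from numbers import Integral, Real

import numpy as np
from sklearn.base import BaseEstimator

from .statistics import N_PB, FrequencyMatrix, delta_pb, frequency_matrix


@dataclass
class SimulationSignature:
    """Per-position PB frequency vector of one simulation."""

    simulation_id: str
    system: str
    probabilities: np.ndarray  # (n_positions, 16); NaN rows undefined
    residue_numbers: np.ndarray | None = None

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.ndim != 2 or self.probabilities.shape[1] != N_PB:
            raise ValueError("probabilities must be (n_positions, 16)")

    @classmethod
    def from_ensemble(cls, ensemble) -> "SimulationSignature":
        fm: FrequencyMatrix = frequency_matrix(ensemble)
        return cls(
            simulation_id=f"{ensemble.system}|{ensemble.run}",
            system=ensemble.system,
            probabilities=fm.probabilities,
            residue_numbers=fm.residue_numbers,
        )

    @property
    def defined(self) -> np.ndarray:
        return ~np.any(np.isnan(self.probabilities), axis=1)


def signature_distance(a: SimulationSignature, b: SimulationSignature) -> float:
    """Normalized mean per-position ΔPB between two simulations, in [0, 1].

    Positions undefined in either signature are skipped; the mean over the
    common defined positions is divided by 2 (the ΔPB maximum), so disjoint
    repertoires at every position give exactly 1.
    """
    if a.probabilities.shape != b.probabilities.shape:
        raise ValueError("signatures must share positions")
    common = a.defined & b.defined
    if not np.any(common):
        raise ValueError("signatures share no defined positions")
    dpb = delta_pb(a.probabilities[common], b.probabilities[common])
    return float(np.mean(dpb) / 2.0)


def distance_matrix(signatures) -> np.ndarray:
    """Symmetric pairwise signature-distance matrix."""
    signatures = list(signatures)
    n = len(signatures)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = signature_distance(signatures[i], signatures[j])
    return D


def _classical_mds(D: np.ndarray, dim: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:dim]
    lam = np.clip(eigval[order], 0.0, None)
    return eigvec[:, order] * np.sqrt(lam)


def _sammon_stress(D: np.ndarray, X: np.ndarray) -> float:
    iu = np.triu_indices_from(D, k=1)
    delta = D[iu]
    d = np.sqrt(np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1))[iu]
    return float(np.sum((delta - d) ** 2 / delta) / np.sum(delta))


class SammonMapping(BaseEstimator):
    """Sammon nonlinear mapping (sklearn-style estimator).

    Parameters
    ----------
    n_components : int, default 2
    max_iter : int, default 500
    tol : float, default 1e-9
        Relative stress-change convergence threshold.
    magic_factor : float, default 0.3
        Damping of Sammon's second-order update.
    init : 'classical' | 'random', default 'classical'
        Classical metric scaling of the dissimilarities, or seeded Gaussian.
    random_state : int, default 0
        Seed for the random init fallback and degenerate-pair jitter.
    eps : float, default 1e-12
        Jitter applied (with a warning) to exactly coincident pairs, whose
        zero dissimilarity the stress cannot weight.

    Attributes (after fit)
    ----------------------
    embedding_ : (n, n_components) coordinates
    stress_ : final Sammon stress
    n_iter_ : accepted iterations
    stress_history_ : stress after init and after each accepted iteration
    """

    def __init__(self, n_components: int = 2, max_iter: int = 500,
                 tol: float = 1e-9, magic_factor: float = 0.3,
                 init: str = "classical", random_state: int = 0,
                 eps: float = 1e-12):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.magic_factor = magic_factor
        self.init = init
        self.random_state = random_state
        self.eps = eps

    def _validate(self, D: np.ndarray) -> np.ndarray:
        D = np.asarray(D, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(D, D.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(D < 0):
            raise ValueError("dissimilarities must be non-negative")
        if np.any(np.diag(D) != 0):
            raise ValueError("dissimilarity diagonal must be zero")
        if not isinstance(self.n_components, Integral) or self.n_components < 1:
            raise ValueError("n_components must be a positive integer")
        if not isinstance(self.tol, Real) or self.tol < 0:
            raise ValueError("tol must be non-negative")
        return D

    def fit(self, D, y=None) -> "SammonMapping":
        """Fit the embedding to a precomputed dissimilarity matrix."""
        D = self._validate(D).copy()
        n = D.shape[0]
        rng = np.random.default_rng(self.random_state)
        if n == 1:
            self.embedding_ = np.zeros((1, self.n_components))
            self.stress_ = 0.0
            self.n_iter_ = 0
            self.stress_history_ = [0.0]
            return self
        off = ~np.eye(n, dtype=bool)
        if np.any(D[off] == 0.0):
            import warnings

            warnings.warn(
                "coincident points (zero dissimilarity) jittered by eps",
                stacklevel=2,
            )
            D[off & (D == 0.0)] = self.eps
        if self.init == "classical":
            X = _classical_mds(D, self.n_components)
            if not np.all(np.isfinite(X)):
                X = rng.normal(scale=1e-2, size=(n, self.n_components))
        elif self.init == "random":
            X = rng.normal(scale=np.mean(D[off]), size=(n, self.n_components))
        else:
            raise ValueError(f"unknown init {self.init!r}")

        c = np.sum(D[np.triu_indices(n, k=1)])
        stress = _sammon_stress(D, X)
        history = [stress]
        n_iter = 0
        for _ in range(self.max_iter):
            d = np.sqrt(np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1))
            d[~off] = 1.0
            d = np.maximum(d, 1e-12)
            # Sammon's diagonal Newton step
            ratio_valid = np.where(off, (D - d) / (d * D + ~off), 0.0)
            diff = X[:, None, :] - X[None, :, :]  # (n, n, k)
            grad = -2.0 / c * np.sum(ratio_valid[:, :, None] * diff, axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(
                    off[:, :, None],
                    ((D - d)[:, :, None]
                     - (diff ** 2) / d[:, :, None]
                     * (1.0 + (D - d)[:, :, None] / d[:, :, None]))
                    / (d * D + ~off)[:, :, None],
                    0.0,
                )
            hess = -2.0 / c * np.sum(term, axis=1)
            step = grad / np.maximum(np.abs(hess), 1e-12)
            # step-halving guard: accept only stress-decreasing updates
            factor = self.magic_factor
            accepted = False
            for _half in range(20):
                X_new = X - factor * step
                new_stress = _sammon_stress(D, X_new)
                if new_stress <= stress:
                    accepted = True
                    break
                factor *= 0.5
            if not accepted:
                break
            n_iter += 1
            X = X_new
            history.append(new_stress)
            if stress - new_stress <= self.tol * max(stress, 1e-300):
                stress = new_stress
                break
            stress = new_stress
        self.embedding_ = X - X.mean(axis=0)
        self.stress_ = stress
        self.n_iter_ = n_iter
        self.stress_history_ = history
        return self

    def fit_transform(self, D, y=None) -> np.ndarray:
        return self.fit(D).embedding_


@dataclass
class SammonEmbedding:
    """2D points per simulation with per-system barycentres and stress."""

    simulation_ids: list[str]
    systems: list[str]
    points: np.ndarray
    stress: float
    n_iter: int
    seed: int

    def barycentres(self) -> dict[str, np.ndarray]:
        return barycentres(self.points, self.systems)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "simulation": self.simulation_ids,
            "system": self.systems,
            "x": self.points[:, 0],
            "y": self.points[:, 1],
        })


def sammon_map(D, simulation_ids=None, systems=None, dim: int = 2,
               seed: int = 0, max_iter: int = 500, tol: float = 1e-9) -> SammonEmbedding:
    """Functional wrapper over :class:`SammonMapping`."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if simulation_ids is None:
        simulation_ids = [f"sim{i}" for i in range(n)]
    if systems is None:
        systems = ["all"] * n
    est = SammonMapping(n_components=dim, max_iter=max_iter, tol=tol,
                        random_state=seed)
    points = est.fit_transform(D)
    return SammonEmbedding(
        simulation_ids=list(simulation_ids),
        systems=list(systems),
        points=points,
        stress=est.stress_,
        n_iter=est.n_iter_,
        seed=seed,
    )


def barycentres(points: np.ndarray, labels) -> dict[str, np.ndarray]:
    """Arithmetic mean of each label's points (insertion-ordered)."""
    points = np.asarray(points, dtype=float)
    labels = list(labels)
    if len(labels) != len(points):
        raise ValueError("one label per point required")
    out: dict[str, np.ndarray] = {}
    for label in dict.fromkeys(labels):
        mask = np.array([l == label for l in labels])
        out[label] = points[mask].mean(axis=0)
    return out
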