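"""Per-atom Gaussian-mixture mode models.

Each atom's 3D coordinate cloud is decomposed into up to ``K_cap`` Gaussian
"modes" — quasi-stable positions (weight pi_k, center mu_k, covariance
Sigma_k).  Fitting uses random-assignment k-means for the initial hard
labels followed by variational-Bayes refinement of a full Gaussian mixture
(Dirichlet prior on the weights, Gaussian–Wishart prior on means and
precisions).  Minor modes with weight below a prune threshold are removed
and the remaining weights renormalised, so a model always stays a proper
probability density.

The VB update loop is provided by scikit-learn's ``BayesianGaussianMixture``;
the subclass below only injects externally computed initial
responsibilities, so the k-means initialisation contract stays in our hands.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.mixture import BayesianGaussianMixture

logger = logging.getLogger(__name__)

#: eigenvalue floor applied to every mode covariance (A^2)
COVARIANCE_FLOOR = 1e-6


@dataclass
class GaussianMode:
    """One Gaussian component: a quasi-stable atomic position."""

    weight: float
    center: np.ndarray          # (3,) A
    covariance: np.ndarray      # (3, 3) SPD, A^2

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.covariance = np.asarray(self.covariance, dtype=float).reshape(3, 3)


@dataclass
class ModeModel:
    """Per-atom Gaussian mixture, modes ordered by descending weight."""

    atom_id: int
    modes: list[GaussianMode]
    fit_meta: dict = field(default_factory=dict)

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    @property
    def weights(self) -> np.ndarray:
        return np.array([m.weight for m in self.modes])

    @property
    def centers(self) -> np.ndarray:
        return np.array([m.center for m in self.modes])

    def log_responsibilities(self, points: np.ndarray) -> np.ndarray:
        """Log posterior mode assignment for each point, ``(M, K)``.

        Computed in log space; if every component underflows at a point the
        point is assigned to the nearest-center mode with probability 1.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        K = self.n_modes
        logp = np.empty((pts.shape[0], K))
        for k, mode in enumerate(self.modes):
            cov = _floor_covariance(mode.covariance)
            L = np.linalg.cholesky(cov)
            dev = np.linalg.solve(L, (pts - mode.center).T).T
            maha = (dev * dev).sum(axis=1)
            logdet = 2.0 * np.log(np.diag(L)).sum()
            logp[:, k] = (np.log(mode.weight) - 0.5 *
                          (maha + logdet + 3 * np.log(2 * np.pi)))
        norm = logsumexp(logp, axis=1, keepdims=True)
        bad = ~np.isfinite(norm[:, 0])
        out = logp - norm
        if bad.any():
            d2 = ((pts[bad, None, :] - self.centers[None]) ** 2).sum(axis=2)
            out[bad] = -np.inf
            out[bad, d2.argmin(axis=1)] = 0.0
        return out

    def responsibilities(self, point: np.ndarray) -> np.ndarray:
        """Posterior assignment vector p_k for one point (sums to 1)."""
        return np.exp(self.log_responsibilities(point))[0]

    def responsibility_matrix(self, points: np.ndarray) -> np.ndarray:
        """``(M, K)`` responsibilities for a coordinate series."""
        return np.exp(self.log_responsibilities(points))


def _floor_covariance(cov: np.ndarray, floor: float = COVARIANCE_FLOOR) -> np.ndarray:
    vals, vecs = np.linalg.eigh(np.asarray(cov, dtype=float))
    if vals.min() >= floor:
        return cov
    vals = np.clip(vals, floor, None)
    return (vecs * vals) @ vecs.T


def kmeans_init(points: np.ndarray, K: int, seed: int,
                max_iter: int = 300) -> np.ndarray:
    """Random-assignment k-means: uniform random labels, then Lloyd.

    Returns hard labels in ``[0, K')`` where ``K' = min(K, M)``; when the
    requested K exceeds the number of points it is reduced with a warning
    rather than failing.
    """
    pts = np.asarray(points, dtype=float)
    M = pts.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if M < K:
        logger.warning("kmeans_init: reducing K from %d to %d (only %d points)",
                       K, M, M)
        K = M
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, K, size=M)
    for _ in range(max_iter):
        centers = np.empty((K, pts.shape[1]))
        for k in range(K):
            member = labels == k
            if member.any():
                centers[k] = pts[member].mean(axis=0)
            else:  # re-seed an empty cluster at a random point
                centers[k] = pts[rng.integers(0, M)]
        d2 = ((pts[:, None, :] - centers[None]) ** 2).sum(axis=2)
        new = d2.argmin(axis=1)
        if np.array_equal(new, labels):
            break
        labels = new
    return labels


class _RespInitVBGMM(BayesianGaussianMixture):
    """BayesianGaussianMixture accepting explicit initial responsibilities."""

    _resp_init: Optional[np.ndarray] = None

    def set_resp_init(self, resp: Optional[np.ndarray]) -> None:
        self._resp_init = resp

    # sklearn private hook; the xp argument is the array-api namespace
    def _initialize_parameters(self, X, random_state, xp=None):
        if self._resp_init is None:
            super()._initialize_parameters(X, random_state, xp=xp)
        else:
            self._initialize(X, self._resp_init)


def _vb_engine(K: int, prior_scale: float, seed: int, tol: float,
               max_iter: int) -> _RespInitVBGMM:
    return _RespInitVBGMM(
        n_components=K,
        covariance_type="full",
        weight_concentration_prior_type="dirichlet_distribution",
        weight_concentration_prior=1.0 / K,
        mean_precision_prior=1.0,
        degrees_of_freedom_prior=4.0,
        covariance_prior=np.eye(3) * prior_scale,
        init_params="random",
        max_iter=max_iter,
        tol=tol,
        reg_covar=COVARIANCE_FLOOR,
        random_state=seed,
    )


def fit_vb_gmm(points: np.ndarray, K_cap: int = 5, seed: int = 0,
               prune_threshold: float = 0.01, *, kmeans_restarts: int = 4,
               random_restarts: int = 1, tol: float = 1e-6,
               max_iter: int = 500, atom_id: int = 0) -> ModeModel:
    """Fit a pruned variational-Bayes Gaussian mixture to one atom's cloud.

    Several initialisations are tried — ``kmeans_restarts`` random-assignment
    k-means label sets plus ``random_restarts`` random-responsibility starts —
    and the solution with the highest evidence lower bound is kept.  The
    random-responsibility start lets the sparsity-leaning Dirichlet prior
    consider fully merged solutions, which k-means labels never propose.

    Modes with weight below ``prune_threshold`` are dropped and the weights
    renormalised; covariance eigenvalues are floored at
    :data:`COVARIANCE_FLOOR`.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"points must be (M, 3), got {pts.shape}")
    if not np.isfinite(pts).all():
        raise ValueError("points contain non-finite values")
    M = pts.shape[0]
    if M < 2:
        raise ValueError("need at least 2 points to fit a mode model")

    meta = {"K_cap": K_cap, "seed": seed}
    span = np.ptp(pts, axis=0).max()
    if span < 1e-9:  # all points identical: single mode with floor covariance
        mode = GaussianMode(1.0, pts[0], np.eye(3) * COVARIANCE_FLOOR)
        meta.update(n_iterations=0, converged=True, elbo_final=float("nan"))
        return ModeModel(atom_id, [mode], meta)

    K = min(K_cap, M)
    prior_scale = max(pts.var(axis=0).mean(), COVARIANCE_FLOOR)
    rng = np.random.default_rng(seed)
    best = None
    plans = ["kmeans"] * kmeans_restarts + ["random"] * random_restarts
    for plan in plans:
        engine = _vb_engine(K, prior_scale, int(rng.integers(2 ** 31)),
                            tol, max_iter)
        if plan == "kmeans":
            labels = kmeans_init(pts, K, int(rng.integers(2 ** 31)))
            resp = np.zeros((M, K))
            resp[np.arange(M), labels] = 1.0
            engine.set_resp_init(resp)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            engine.fit(pts)
        if best is None or engine.lower_bound_ > best.lower_bound_:
            best = engine

    modes = [GaussianMode(w, mu, _floor_covariance(cov))
             for w, mu, cov in zip(best.weights_, best.means_,
                                   best.covariances_)]
    modes.sort(key=lambda m: m.weight, reverse=True)
    meta.update(n_iterations=int(best.n_iter_), converged=bool(best.converged_),
                elbo_final=float(best.lower_bound_))
    model = ModeModel(atom_id, modes, meta)
    return prune_modes(model, prune_threshold)


def prune_modes(model: ModeModel, threshold: float) -> ModeModel:
    """Drop modes with weight below ``threshold`` and renormalise.

    The largest mode is always retained, so the model can never become
    empty.
    """
    kept = [m for m in model.modes if m.weight >= threshold]
    if not kept:
        kept = [max(model.modes, key=lambda m: m.weight)]
    total = sum(m.weight for m in kept)
    new = [GaussianMode(m.weight / total, m.center.copy(), m.covariance.copy())
           for m in kept]
    new.sort(key=lambda m: m.weight, reverse=True)
    return ModeModel(model.atom_id, new, dict(model.fit_meta))


def responsibilities(model: ModeModel, point: np.ndarray) -> np.ndarray:
    """Functional form of :meth:`ModeModel.responsibilities`."""
    return model.responsibilities(point)


@dataclass
class FitConfig:
    """Configuration for :func:`fit_all_atoms`."""

    K_cap: int = 5
    prune_threshold: float = 0.01
    seed: int = 0
    kmeans_restarts: int = 4
    random_restarts: int = 1
    tol: float = 1e-6
    max_iter: int = 500


def _atom_seed(base_seed: int, atom_id: int) -> int:
    """Deterministic per-atom seed, independent of execution order."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(atom_id,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def fit_all_atoms(traj, config: Optional[FitConfig] = None) -> list[ModeModel]:
    """One independent :class:`ModeModel` per atom of a trajectory.

    Per-atom seeds are derived deterministically from the base seed and the
    atom id, so results do not depend on iteration order.  A per-atom
    failure falls back to a single-mode model (logged) instead of aborting
    the whole run.
    """
    config = config or FitConfig()
    models = []
    for atom_id in range(traj.n_atoms):
        pts = traj.atom_coords(atom_id)
        seed = _atom_seed(config.seed, atom_id)
        try:
            model = fit_vb_gmm(pts, K_cap=config.K_cap, seed=seed,
                               prune_threshold=config.prune_threshold,
                               kmeans_restarts=config.kmeans_restarts,
                               random_restarts=config.random_restarts,
                               tol=config.tol, max_iter=config.max_iter,
                               atom_id=atom_id)
        except Exception as exc:
            logger.warning("atom %d: VB fit failed (%s); falling back to "
                           "single-mode model", atom_id, exc)
            model = _single_mode(pts, atom_id)
        models.append(model)
    return models


def _single_mode(points: np.ndarray, atom_id: int) -> ModeModel:
    pts = np.asarray(points, dtype=float)
    cov = _floor_covariance(np.cov(pts.T)) if pts.shape[0] > 1 \
        else np.eye(3) * COVARIANCE_FLOOR
    return ModeModel(atom_id, [GaussianMode(1.0, pts.mean(axis=0), cov)],
                     {"K_cap": 1, "seed": 0, "n_iterations": 0,
                      "converged": True, "elbo_final": float("nan")})


def single_mode_models(traj) -> list[ModeModel]:
    """Force one mode per atom at the sample mean (DCC-equivalent models).

    With a single mode every responsibility is identically 1, so the
    weighted-cosine mode correlation collapses to the conventional DCC.
    """
    return [_single_mode(traj.atom_coords(i), i) for i in range(traj.n_atoms)]


def mode_count_summary(models: Sequence[ModeModel]) -> dict:
    """Histogram of surviving mode counts and pooled weight distribution."""
    counts = np.array([m.n_modes for m in models])
    weights = np.concatenate([m.weights for m in models])
    hist = {int(k): int((counts == k).sum()) for k in np.unique(counts)}
    return {"n_atoms": len(models), "n_modes_total": int(counts.sum()),
            "mode_count_histogram": hist,
            "weight_quantiles": {q: float(np.quantile(weights, q))
                                 for q in (0.05, 0.25, 0.5, 0.75, 0.95)}}


def save_mode_models(models: Sequence[ModeModel], path, atoms=None) -> None:
    """Write mode models to JSON (row-major covariance, full precision)."""
    doc = []
    for m in models:
        entry = {
            "atom_id": int(m.atom_id),
            "modes": [{"weight": float(g.weight),
                       "center": [float(x) for x in g.center],
                       "covariance": [[float(x) for x in row]
                                      for row in g.covariance]}
                      for g in m.modes],
            "fit_meta": {k: (None if isinstance(v, float) and np.isnan(v)
                             else v) for k, v in m.fit_meta.items()},
        }
        if atoms is not None:
            row = atoms.iloc[m.atom_id]
            entry["atom"] = {"atom_name": str(row["atom_name"]),
                             "chain_id": str(row["chain_id"]),
                             "residue_seq": int(row["residue_seq"]),
                             "residue_name": str(row["residue_name"])}
        doc.append(entry)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_mode_models(path) -> list[ModeModel]:
    with open(path) as fh:
        doc = json.load(fh)
    models = []
    for entry in doc:
        modes = [GaussianMode(g["weight"], np.array(g["center"]),
                              np.array(g["covariance"]))
                 for g in entry["modes"]]
        models.append(ModeModel(entry["atom_id"], modes,
                                entry.get("fit_meta", {})))
    return models
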