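"""Bayesian inference of chromatin parameters from measurement datasets.

The posterior is ``p(Pi, Xi | D) ~ p(D | Pi, Xi) p(Pi) p(Xi)`` with a
Gaussian likelihood per measurement, flat priors for the structural
parameters Pi = (P, C, W, L) over the grid box, and one noise-scale nuisance
parameter Xi_g per data group (live imaging, fixed imaging, and each Hi-C
study) with a broad half-normal prior.  Sampling uses the affine-invariant
ensemble (stretch-move) MCMC sampler; marginals, MAP estimates and
highest-density credible regions are computed from the smoothed draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import emcee
import numpy as np
from scipy.stats import gaussian_kde

from .genome import ParameterPoint
from .grid import AXES, ModelGrid
from .observables import ObservableSet

__all__ = [
    "Dataset",
    "NuisanceModel",
    "PosteriorSample",
    "Density",
    "log_likelihood",
    "make_log_posterior",
    "run_ensemble_mcmc",
    "marginal_density",
    "map_estimate",
    "credible_region",
    "region_polygons",
    "infer_parameters",
    "InferenceResult",
]

#: A measurement dataset shares the observable-table schema.
Dataset = ObservableSet


@dataclass(frozen=True)
class NuisanceModel:
    """Variance model: sigma_k = xi_g * s_k with one scale xi_g per group.

    ``s_k`` is an observable magnitude (floored at a small fraction of the
    group median so near-zero values keep a positive variance), which makes
    xi_g a relative noise level for distances/angles and for contact
    frequencies alike.  During inference ``s_k`` defaults to the magnitude of
    the current model prediction, which matches the multiplicative-noise
    generative picture; scaling by the measured value instead lets any datum
    that noise happens to deflate shrink its own error bar and gain spurious
    weight (both variants, and a lattice-averaged fixed scale, are selectable
    via ``make_log_posterior(sigma_scale=...)`` and were compared on repeated
    synthetic recoveries).  The prior on each xi_g is half-normal.
    """

    groups: tuple[str, ...]
    scale_floor_frac: float = 0.05
    prior_scale: float = 0.5

    @classmethod
    def for_dataset(cls, dataset: Dataset, **kw) -> "NuisanceModel":
        groups = tuple(dict.fromkeys(s.group for s in dataset.specs))
        return cls(groups=groups, **kw)

    @property
    def n_params(self) -> int:
        return len(self.groups)

    def base_scales(self, dataset: Dataset) -> np.ndarray:
        """Per-measurement magnitude s_k (measurement-based convenience form)."""
        s = np.abs(dataset.values).astype(float)
        return np.maximum(s, self.scale_floors(dataset))

    def scale_floors(self, dataset: Dataset) -> np.ndarray:
        """Per-observable lower bound on the magnitude scale (a fraction of
        the group's median measurement)."""
        s = np.abs(dataset.values).astype(float)
        gidx = self.group_indices(dataset)
        floors = np.empty_like(s)
        for g in range(len(self.groups)):
            m = gidx == g
            med = np.median(s[m]) if m.any() else 1.0
            floors[m] = self.scale_floor_frac * max(med, 1e-12)
        return floors

    def group_indices(self, dataset: Dataset) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.groups)}
        return np.array([lookup[s.group] for s in dataset.specs])

    def sigmas(self, xi: np.ndarray, dataset: Dataset) -> np.ndarray:
        return xi[self.group_indices(dataset)] * self.base_scales(dataset)

    def log_prior(self, xi: np.ndarray) -> float:
        if np.any(xi <= 0):
            return -np.inf
        return float(-0.5 * np.sum((xi / self.prior_scale) ** 2))


def log_likelihood(data_values, pred_values, sigmas) -> float:
    """Independent Gaussian log-likelihood sum_k N(Y_k^E | Y_k^M, sigma_k^2)."""
    y = np.asarray(data_values, float)
    mu = np.asarray(pred_values, float)
    s = np.asarray(sigmas, float)
    if y.shape != mu.shape:
        raise ValueError("data and predictions must align")
    if np.any(s <= 0):
        raise ValueError("non-positive variance")
    r = (y - mu) / s
    return float(np.sum(-0.5 * r**2 - 0.5 * np.log(2.0 * np.pi * s**2)))


@dataclass
class PosteriorSample:
    """Flattened MCMC draws over (structural parameters, nuisance scales)."""

    draws: np.ndarray                # (n_draws, ndim)
    log_prob: np.ndarray
    param_names: tuple[str, ...]
    fixed: dict[str, float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def column(self, name: str) -> np.ndarray:
        return self.draws[:, self.param_names.index(name)]

    def structural_draws(self, names: Sequence[str]) -> np.ndarray:
        cols = []
        for n in names:
            if n in self.param_names:
                cols.append(self.column(n))
            else:
                cols.append(np.full(self.draws.shape[0], self.fixed[n]))
        return np.column_stack(cols)


def make_log_posterior(
    grid: ModelGrid,
    dataset: Dataset,
    nuisance: NuisanceModel | None = None,
    prior_bounds: dict[str, tuple[float, float]] | None = None,
    sigma_scale: str = "prediction",
):
    """Batched log-posterior over (active structural axes, nuisance scales).

    Structural axes with a single grid value are held fixed; the flat prior
    box defaults to the grid hull (the sampler must not extrapolate the
    surrogate).  Returns ``(log_prob_fn, param_names, fixed, bounds)``.
    """
    nuisance = nuisance or NuisanceModel.for_dataset(dataset)
    grid_ids = [s.id for s in grid.schema]
    order = []
    for s in dataset.specs:
        if s.id not in grid_ids:
            raise KeyError(f"dataset observable {s.id!r} missing from grid schema")
        order.append(grid_ids.index(s.id))
    order = np.array(order)

    active = [a for a in AXES if grid.axes[a].size > 1]
    fixed = {a: float(grid.axes[a][0]) for a in AXES if grid.axes[a].size == 1}
    bounds = dict(grid.bounds) if prior_bounds is None else dict(prior_bounds)
    names = tuple(active) + tuple(f"xi_{g}" for g in nuisance.groups)
    n_act = len(active)

    y = dataset.values.copy()
    floors = nuisance.scale_floors(dataset)
    gidx = nuisance.group_indices(dataset)
    rel_spread = grid.relative_spread()[order]
    # fixed per-observable magnitude scale: lattice-averaged |prediction|
    flat_nodes = grid.node_values.reshape(-1, grid.node_values.shape[-1])
    typical = np.maximum(np.abs(flat_nodes).mean(axis=0)[order], floors)

    lo = np.array([bounds[a][0] for a in active])
    hi = np.array([bounds[a][1] for a in active])
    glo = np.array([grid.axes[a][0] for a in active])
    ghi = np.array([grid.axes[a][-1] for a in active])
    lo = np.maximum(lo, glo)
    hi = np.minimum(hi, ghi)

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        out = np.full(theta.shape[0], -np.inf)
        struct = theta[:, :n_act]
        xi = theta[:, n_act:]
        valid = np.all((struct >= lo) & (struct <= hi), axis=1) & np.all(xi > 0, axis=1)
        if not valid.any():
            return out if theta.shape[0] > 1 else out[0]
        pts = np.empty((int(valid.sum()), 4))
        for d, a in enumerate(AXES):
            if a in fixed:
                pts[:, d] = fixed[a]
            else:
                pts[:, d] = struct[valid, active.index(a)]
        preds = grid.predict_values(pts)[:, order]
        if sigma_scale == "prediction":
            base = np.maximum(np.abs(preds), floors[None, :])
        elif sigma_scale == "measurement":
            base = np.maximum(np.abs(y), floors)[None, :]
        else:
            base = typical[None, :]
        s = base * np.sqrt(xi[valid][:, gidx] ** 2 + rel_spread[None, :] ** 2)
        r = (y[None, :] - preds) / s
        ll = np.sum(-0.5 * r**2 - 0.5 * np.log(2.0 * np.pi * s**2), axis=1)
        lp = -0.5 * np.sum((xi[valid] / nuisance.prior_scale) ** 2, axis=1)
        out[valid] = ll + lp
        return out if theta.shape[0] > 1 else out[0]

    return log_prob, names, fixed, {a: (float(l), float(h)) for a, l, h in zip(active, lo, hi)}


def run_ensemble_mcmc(
    log_prob: Callable[[np.ndarray], np.ndarray],
    initial: np.ndarray,
    n_steps: int = 2000,
    seed: int = 0,
    burn_frac: float = 0.3,
    thin: int = 1,
    min_acceptance: float = 0.05,
) -> PosteriorSample:
    """Affine-invariant ensemble sampling from a walker initialization.

    ``initial`` has shape (n_walkers, ndim) with n_walkers >= 2 * ndim.
    Burn-in is discarded and an all-walkers-stuck condition (mean acceptance
    below ``min_acceptance``) raises.  The integrated autocorrelation time is
    estimated and stored in the metadata; draws are kept unthinned by default
    (kernel density summaries tolerate correlated draws).
    """
    initial = np.asarray(initial, float)
    n_walkers, ndim = initial.shape
    if n_walkers < 2 * ndim:
        raise ValueError("need n_walkers >= 2 * ndim")
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob, vectorize=True)
    sampler.random_state = np.random.RandomState(seed % 2**31).get_state()
    sampler.run_mcmc(initial, n_steps, progress=False, skip_initial_state_check=True)
    acc = float(np.mean(sampler.acceptance_fraction))
    if acc < min_acceptance:
        raise RuntimeError(f"sampler stuck: mean acceptance {acc:.3f} < {min_acceptance}")
    burn = int(burn_frac * n_steps)
    try:
        import contextlib
        import io as _io

        with contextlib.redirect_stderr(_io.StringIO()):
            tau = float(np.nanmax(sampler.get_autocorr_time(discard=burn, quiet=True)))
    except Exception:
        tau = float("nan")
    thin_val = max(1, int(thin))
    draws = sampler.get_chain(discard=burn, thin=thin_val, flat=True)
    logp = sampler.get_log_prob(discard=burn, thin=thin_val, flat=True)
    return PosteriorSample(
        draws=draws,
        log_prob=logp,
        param_names=tuple(f"p{i}" for i in range(ndim)),
        metadata={"n_walkers": n_walkers, "n_steps": n_steps, "burn": burn, "thin": thin_val,
                  "seed": seed, "acceptance": acc, "autocorr_time": tau},
    )


@dataclass
class Density:
    """Kernel-smoothed density on a rectangular grid (1D or 2D)."""

    names: tuple[str, ...]
    grids: tuple[np.ndarray, ...]
    values: np.ndarray
    bandwidths: tuple[float, ...]

    @property
    def cell_volume(self) -> float:
        return float(np.prod([g[1] - g[0] for g in self.grids]))

    def integral(self) -> float:
        return float(self.values.sum() * self.cell_volume)

    def level_for_mass(self, mass: float) -> float:
        """Density level whose superlevel set encloses the requested mass."""
        if not (0 < mass < 1):
            raise ValueError("mass must be in (0, 1)")
        flat = np.sort(self.values.ravel())[::-1]
        cum = np.cumsum(flat) * self.cell_volume
        k = int(np.searchsorted(cum, mass))
        return float(flat[min(k, flat.size - 1)])

    def argmax(self) -> tuple[float, ...]:
        idx = np.unravel_index(np.argmax(self.values), self.values.shape)
        return tuple(float(g[i]) for g, i in zip(self.grids, idx))

    def at(self, point: Sequence[float]) -> float:
        """Nearest-cell density value at a point."""
        idx = tuple(
            int(np.clip(np.searchsorted(g, p), 0, g.size - 1)) for g, p in zip(self.grids, point)
        )
        return float(self.values[idx])

    def contains(self, point: Sequence[float], mass: float) -> bool:
        """Is the point inside the highest-density region of given mass?"""
        return self.at(point) >= self.level_for_mass(mass)


def marginal_density(
    sample: PosteriorSample,
    names: Sequence[str],
    bounds: dict[str, tuple[float, float]] | None = None,
    grid_size: int = 121,
    max_draws: int = 6000,
    min_draws: int = 1000,
) -> Density:
    """Kernel density of a 1- or 2-parameter marginal of the posterior.

    Draws near a hard prior bound are mirrored across it before smoothing so
    the density does not artificially decay at the boundary.  The result is
    normalized to integrate to 1 on its own grid.
    """
    cols = np.column_stack([sample.column(n) for n in names])
    if cols.shape[0] < min_draws:
        raise ValueError(f"need >= {min_draws} draws, have {cols.shape[0]}")
    if cols.shape[0] > max_draws:
        step = cols.shape[0] // max_draws + 1
        cols = cols[::step]
    d = cols.shape[1]
    if d > 2:
        raise ValueError("marginal_density supports 1 or 2 parameters")

    sd = cols.std(axis=0, ddof=1)
    n = cols.shape[0]
    bw = sd * n ** (-1.0 / (d + 4))  # Silverman/Scott scale per axis

    # reflect near bounds
    aug = cols
    if bounds:
        for j, name in enumerate(names):
            if name not in bounds:
                continue
            lo, hi = bounds[name]
            for edge, side in ((lo, 1), (hi, -1)):
                near = np.abs(cols[:, j] - edge) < 3.0 * max(bw[j], 1e-12)
                if near.any():
                    ref = cols[near].copy()
                    ref[:, j] = 2.0 * edge - ref[:, j]
                    aug = np.vstack([aug, ref])

    grids = []
    for j, name in enumerate(names):
        if bounds and name in bounds:
            lo, hi = bounds[name]
        else:
            lo, hi = cols[:, j].min() - 3 * bw[j], cols[:, j].max() + 3 * bw[j]
        grids.append(np.linspace(lo, hi, grid_size))

    kde = gaussian_kde(aug.T, bw_method="silverman")
    if d == 1:
        vals = kde(grids[0][None, :])
    else:
        mesh = np.meshgrid(*grids, indexing="ij")
        vals = kde(np.vstack([m.ravel() for m in mesh])).reshape(grid_size, grid_size)
    vals = np.maximum(vals, 0.0)
    cell = float(np.prod([g[1] - g[0] for g in grids]))
    total = vals.sum() * cell
    vals = vals / total
    return Density(tuple(names), tuple(grids), vals, tuple(float(b) for b in bw))


def map_estimate(
    sample: PosteriorSample,
    names: Sequence[str] = ("P", "C"),
    bounds: dict[str, tuple[float, float]] | None = None,
    method: str = "marginal",
) -> dict:
    """MAP estimate: argmax of the smoothed joint marginal (default), or the
    best raw draw.  Flags possible multimodality of the smoothed marginal."""
    names = [n for n in names if n in sample.param_names]
    if method == "best_draw":
        best = sample.draws[int(np.argmax(sample.log_prob))]
        est = {n: float(best[sample.param_names.index(n)]) for n in names}
        return {"estimate": est, "method": "best_draw", "multimodal": False}
    dens = marginal_density(sample, names, bounds=bounds)
    peak = dens.argmax()
    est = dict(zip(names, peak))
    multimodal = _is_multimodal(dens)
    return {"estimate": est, "method": "marginal", "multimodal": multimodal, "density": dens}


def _is_multimodal(dens: Density, rel_height: float = 0.8) -> bool:
    """Detect a secondary local maximum comparable to the global one."""
    v = dens.values
    if v.ndim == 1:
        interior = v[1:-1]
        peaks = (interior > v[:-2]) & (interior > v[2:])
        vals = np.sort(interior[peaks])[::-1]
    else:
        core = v[1:-1, 1:-1]
        peaks = (
            (core >= v[:-2, 1:-1]) & (core >= v[2:, 1:-1])
            & (core >= v[1:-1, :-2]) & (core >= v[1:-1, 2:])
        )
        vals = np.sort(core[peaks])[::-1]
    return bool(vals.size >= 2 and vals[1] >= rel_height * vals[0])


def credible_region(dens: Density, mass: float) -> dict:
    """Highest-density region of the requested probability mass.

    Returns the iso-density level, the boolean superlevel mask on the density
    grid, and the enclosed mass actually realized (quadrature on the grid).
    """
    level = dens.level_for_mass(mass)
    mask = dens.values >= level
    enclosed = float(dens.values[mask].sum() * dens.cell_volume)
    return {"mass": mass, "level": level, "mask": mask, "enclosed": enclosed}


def region_polygons(dens: Density, mass: float) -> list[np.ndarray]:
    """Iso-density contour(s) of a 2D credible region as polygon vertex lists
    in parameter coordinates (one (n, 2) array per closed contour)."""
    if dens.values.ndim != 2:
        raise ValueError("polygons require a 2D density")
    from skimage import measure

    level = dens.level_for_mass(mass)
    polys = []
    for contour in measure.find_contours(dens.values, level):
        xy = np.column_stack(
            [np.interp(contour[:, 0], np.arange(dens.grids[0].size), dens.grids[0]),
             np.interp(contour[:, 1], np.arange(dens.grids[1].size), dens.grids[1])]
        )
        polys.append(xy)
    return polys


# ---------------------------------------------------------------------------
# high-level driver


@dataclass
class InferenceResult:
    sample: PosteriorSample
    map: dict
    marginal: Density
    regions: dict
    bounds: dict


def infer_parameters(
    grid: ModelGrid,
    dataset: Dataset,
    n_walkers: int = 32,
    n_steps: int = 2000,
    seed: int = 0,
    nuisance: NuisanceModel | None = None,
    marginal_names: Sequence[str] = ("P", "C"),
    xi_init: float = 0.15,
) -> InferenceResult:
    """End-to-end inference: sample the posterior over (active Pi, Xi) and
    summarize the requested structural marginal (default (P, C))."""
    nuisance = nuisance or NuisanceModel.for_dataset(dataset)
    log_prob, names, fixed, bounds = make_log_posterior(grid, dataset, nuisance)
    ndim = len(names)
    n_walkers = max(n_walkers, 2 * ndim + 2)
    rng = np.random.default_rng(seed)
    n_act = ndim - nuisance.n_params

    # coarse scan over the lattice nodes to seed the walkers near the mode,
    # with enough jitter to populate any posterior ridge
    cand = np.array(
        [
            [getattr(p, a) for a in names[:n_act]] + [xi_init] * nuisance.n_params
            for p in grid.points
        ]
    )
    best = cand[int(np.argmax(log_prob(cand)))]
    init = np.empty((n_walkers, ndim))
    for j, a in enumerate(names[:n_act]):
        lo, hi = bounds[a]
        width = 0.15 * (hi - lo)
        init[:, j] = np.clip(best[j] + width * rng.standard_normal(n_walkers), lo, hi)
    init[:, n_act:] = xi_init * np.exp(0.3 * rng.standard_normal((n_walkers, nuisance.n_params)))
    sample = run_ensemble_mcmc(log_prob, init, n_steps=n_steps, seed=seed + 1)
    sample.param_names = tuple(names)
    sample.fixed = fixed
    mnames = [n for n in marginal_names if n in names]
    mp = map_estimate(sample, mnames, bounds=bounds)
    dens = mp.get("density") or marginal_density(sample, mnames, bounds=bounds)
    regions = {m: credible_region(dens, m) for m in (0.68, 0.95)}
    for a in fixed:
        mp["estimate"].setdefault(a, fixed[a])
    return InferenceResult(sample=sample, map=mp, marginal=dens, regions=regions, bounds=bounds)
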