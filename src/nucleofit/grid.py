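"""Library of simulations over a lattice of structural parameters, with
multilinear interpolation of predicted observables at arbitrary (P, C, W, L).

The grid is the surrogate that makes Bayesian inference tractable: each
lattice node carries replica-averaged observable predictions, and queries
inside the lattice hull are answered by piecewise-multilinear interpolation,
which is exact at the nodes and monotonicity-preserving within each cell.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .genome import GenomeSpec, NucleusGeometry, ParameterPoint, discretize_genome
from .observables import ObservableSet, ObservableSpec, compute_observables
from .simulate import ForceField, build_system, run_simulation

__all__ = ["SimulationConfig", "ModelGrid", "build_grid", "predict_observables", "replica_convergence_report"]

AXES = ("P", "C", "W", "L")


@dataclass(frozen=True)
class SimulationConfig:
    """Per-node simulation settings for grid construction."""

    n_steps: int = 300_000
    sample_every: int = 1_000
    equilibration_steps: int = 100_000
    n_replicas: int = 2
    dt: Optional[float] = None
    contact_cutoff_nm: Optional[float] = None
    force_field: ForceField = field(default_factory=ForceField)

    def digest(self) -> str:
        return hashlib.sha1(repr(self).encode()).hexdigest()[:12]


@dataclass
class ModelGrid:
    """Observable predictions on a (P, C, W, L) lattice.

    ``axes`` maps each parameter name to its sorted unique lattice values;
    ``node_values`` has shape ``(nP, nC, nW, nL, n_obs)`` with replica means,
    ``node_spread`` the replica standard errors, and ``replica_values`` keeps
    the per-replica sets for convergence checks and held-out validation.
    """

    schema: tuple[ObservableSpec, ...]
    axes: dict[str, np.ndarray]
    node_values: np.ndarray
    node_spread: np.ndarray
    replica_values: dict[tuple[float, float, float, float], list[ObservableSet]] = field(
        default_factory=dict
    )
    metadata: dict = field(default_factory=dict)
    _interp: Optional[RegularGridInterpolator] = None
    _spread_interp: Optional[RegularGridInterpolator] = None

    def __post_init__(self):
        if np.isnan(self.node_values).any():
            bad = np.argwhere(np.isnan(self.node_values[..., 0]))
            raise ValueError(f"grid has unusable nodes at lattice indices {bad.tolist()}")

    @property
    def points(self) -> list[ParameterPoint]:
        pts = []
        for P in self.axes["P"]:
            for C in self.axes["C"]:
                for W in self.axes["W"]:
                    for L in self.axes["L"]:
                        pts.append(ParameterPoint(P, C, W, L))
        return pts

    @property
    def bounds(self) -> dict[str, tuple[float, float]]:
        return {k: (float(v[0]), float(v[-1])) for k, v in self.axes.items()}

    def interpolator(self) -> RegularGridInterpolator:
        if self._interp is None:
            # collapse singleton axes for scipy, reinserted at query time
            self._interp = RegularGridInterpolator(
                tuple(self.axes[a] for a in AXES if self.axes[a].size > 1),
                self.node_values.squeeze(
                    axis=tuple(i for i, a in enumerate(AXES) if self.axes[a].size == 1)
                ),
                method="linear",
                bounds_error=True,
            )
        return self._interp

    def predict(self, point: ParameterPoint) -> ObservableSet:
        return predict_observables(self, point)

    def predict_values(self, pts: np.ndarray) -> np.ndarray:
        """Vectorized prediction for an (n, 4) array of (P, C, W, L) rows."""
        pts = np.atleast_2d(np.asarray(pts, float))
        for d, a in enumerate(AXES):
            ax = self.axes[a]
            lo, hi = ax[0], ax[-1]
            if np.any(pts[:, d] < lo - 1e-9) or np.any(pts[:, d] > hi + 1e-9):
                raise ValueError(f"query outside grid range on axis {a} [{lo}, {hi}]")
        cols = [d for d, a in enumerate(AXES) if self.axes[a].size > 1]
        if not cols:  # every axis fixed: the single node answers all queries
            return np.broadcast_to(
                self.node_values.reshape(1, -1), (pts.shape[0], self.node_values.size)
            ).copy()
        return self.interpolator()(pts[:, cols])

    def relative_spread(self) -> np.ndarray:
        """Per-observable relative replica standard error, pooled (median)
        over all lattice nodes.

        With few replicas the per-node spread estimate is extremely noisy;
        pooling across nodes gives a usable estimate of the surrogate's own
        sampling uncertainty for each observable.
        """
        flat_vals = self.node_values.reshape(-1, self.node_values.shape[-1])
        flat_spread = self.node_spread.reshape(-1, self.node_spread.shape[-1])
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(np.abs(flat_vals) > 1e-12, flat_spread / np.abs(flat_vals), 0.0)
        return np.median(rel, axis=0)

    def manifest(self) -> pd.DataFrame:
        rows = []
        for key, reps in self.replica_values.items():
            P, C, W, L = key
            rows.append(
                dict(P=P, C=C, W=W, L=L, n_replicas=len(reps),
                     seeds=",".join(str(s) for s in self.metadata.get("seeds", {}).get(key, [])),
                     status="ok")
            )
        return pd.DataFrame(rows)

    def write_manifest(self, path: str | Path) -> None:
        self.manifest().to_csv(path, sep="\t", index=False)


def build_grid(
    parameter_points: Sequence[ParameterPoint],
    genome: GenomeSpec,
    geometry: NucleusGeometry,
    schema: Sequence[ObservableSpec],
    config: SimulationConfig | None = None,
    seed: int = 0,
    progress: Callable[[str], None] | None = None,
    cache_dir: str | Path | None = None,
) -> ModelGrid:
    """Run (replica) simulations at every lattice node and assemble the grid.

    ``parameter_points`` must fill a full cartesian lattice (every combination
    of the per-axis unique values present).  Replicas differ only by seed.
    With ``cache_dir`` set, each node's replica observables are checkpointed
    (keyed by parameter point, seed, and config hash), so an interrupted
    large-grid build resumes where it stopped.
    """
    config = config or SimulationConfig()
    pts = np.array([[p.P, p.C, p.W, p.L] for p in parameter_points])
    axes = {a: np.unique(pts[:, d]) for d, a in enumerate(AXES)}
    expected = int(np.prod([v.size for v in axes.values()]))
    if expected != len(parameter_points):
        raise ValueError(
            f"{len(parameter_points)} points do not fill the {expected}-node cartesian lattice"
        )

    shape = tuple(axes[a].size for a in AXES) + (len(schema),)
    node_values = np.full(shape, np.nan)
    node_spread = np.full(shape, np.nan)
    replica_values: dict = {}
    seeds_used: dict = {}

    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)

    for p_idx, point in enumerate(parameter_points):
        chains = discretize_genome(genome, point, geometry)
        system = build_system(chains, geometry, point, config.force_field)
        reps = []
        seeds = []
        for r in range(config.n_replicas):
            run_seed = (seed * 100_003 + p_idx * 613 + r * 7919) % 2**31
            seeds.append(run_seed)
            cache_file = None
            if cache is not None:
                key = f"{point.P}_{point.C}_{point.W}_{point.L}_{run_seed}_{config.digest()}"
                cache_file = cache / f"node_{hashlib.sha1(key.encode()).hexdigest()[:16]}.pkl"
                if cache_file.exists():
                    import pickle

                    with open(cache_file, "rb") as fh:
                        reps.append(pickle.load(fh))
                    continue
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                traj = run_simulation(
                    system,
                    n_steps=config.n_steps,
                    sample_every=config.sample_every,
                    equilibration_steps=config.equilibration_steps,
                    seed=run_seed,
                    dt=config.dt,
                )
            obs = compute_observables(
                traj, schema, contact_cutoff_nm=config.contact_cutoff_nm, seed=run_seed
            )
            if cache_file is not None:
                import pickle

                with open(cache_file, "wb") as fh:
                    pickle.dump(obs, fh)
            reps.append(obs)
            del traj
        key = (point.P, point.C, point.W, point.L)
        replica_values[key] = reps
        seeds_used[key] = seeds
        vals = np.stack([r.values for r in reps])
        idx = tuple(int(np.searchsorted(axes[a], getattr(point, a))) for a in AXES)
        node_values[idx] = vals.mean(axis=0)
        node_spread[idx] = vals.std(axis=0, ddof=1) / np.sqrt(len(reps)) if len(reps) > 1 else 0.0
        if progress is not None:
            progress(f"node {p_idx + 1}/{len(parameter_points)} {key} done")

    return ModelGrid(
        schema=tuple(schema),
        axes=axes,
        node_values=node_values,
        node_spread=node_spread,
        replica_values=replica_values,
        metadata={"seeds": seeds_used, "config": config, "config_hash": config.digest(), "seed": seed},
    )


def predict_observables(grid: ModelGrid, point: ParameterPoint) -> ObservableSet:
    """Interpolated observable predictions at an arbitrary interior point."""
    vals = grid.predict_values(np.array([[point.P, point.C, point.W, point.L]]))[0]
    return ObservableSet(grid.schema, vals)


def replica_convergence_report(grid: ModelGrid, cv_threshold: float = 0.25) -> pd.DataFrame:
    """Between-replica coefficient of variation per node, with a flag for
    nodes whose replicas disagree beyond the threshold on many observables."""
    rows = []
    for key, reps in grid.replica_values.items():
        if len(reps) < 2:
            raise ValueError("convergence report needs >= 2 replicas per node")
        vals = np.stack([r.values for r in reps])
        mean = vals.mean(axis=0)
        sd = vals.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(np.abs(mean) > 1e-12, sd / np.abs(mean), 0.0)
        rows.append(
            dict(P=key[0], C=key[1], W=key[2], L=key[3], n_replicas=len(reps),
                 median_cv=float(np.median(cv)), max_cv=float(cv.max()),
                 flagged=bool(np.median(cv) > cv_threshold))
        )
    return pd.DataFrame(rows)
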