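import warnings

import numpy as np
import pytest

from nucleofit.genome import ParameterPoint
from nucleofit.grid import build_grid
from nucleofit.validate import (
    scaled_genome,
    scaled_geometry,
    scaled_grid_points,
    scaled_schema,
    scaled_sim_config,
)


@pytest.fixture(scope="session")
def yeast():
    from nucleofit.genome import yeast_genome

    return yeast_genome()


@pytest.fixture(scope="session")
def scaled_grid():
    """The desk-scale (P, C) simulation grid used by the validation harness.

    Built once per session (a few minutes of Langevin dynamics); shared by
    the recovery, ridge, and interpolation tests.
    """
    genome = scaled_genome()
    geometry = scaled_geometry()
    schema = scaled_schema(genome)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return build_grid(
            scaled_grid_points(), genome, geometry, schema, scaled_sim_config(), seed=11
        )


@pytest.fixture(scope="session")
def phantom_traj():
    """Ensemble trajectory of freely jointed 200-bead phantom chains for the
    polymer-scaling checks."""
    from nucleofit.validate import phantom_chain_ensemble

    return phantom_chain_ensemble(n_chains=12, n_beads=200, n_steps=2_400_000,
                                  sample_every=2_000, seed=5)


@pytest.fixture(scope="session")
def phantom_static_traj():
    """Wide, short-run phantom-chain ensemble for equilibrium (static)
    scaling checks: chains start in their exact equilibrium ensemble, so a
    broad ensemble with brief dynamics measures static exponents far more
    precisely than a long trajectory of few chains."""
    from nucleofit.validate import phantom_chain_ensemble

    return phantom_chain_ensemble(n_chains=48, n_beads=200, n_steps=80_000,
                                  sample_every=2_000, seed=18)


@pytest.fixture(scope="session")
def toy_grid():
    """Analytic surrogate grid (synthetic stand-in, no simulations): observables
    are smooth closed-form functions of (P, C), mimicking how distances grow
    with rigidity and shrink with compaction."""
    from nucleofit.grid import ModelGrid
    from nucleofit.observables import ObservableSpec

    rng = np.random.default_rng(42)
    n_obs = 48
    specs = []
    kinds = []
    for k in range(n_obs):
        group = ("live_imaging", "fixed_imaging", "hic_A")[k % 3]
        cls = "median_3d_distance" if group != "hic_A" else "contact_vs_s_genomewide"
        specs.append(
            ObservableSpec(id=f"toy{k}", cls=cls, chrom_a="chrA", bp_a=1000 * k,
                           chrom_b="chrA", bp_b=1000 * k + 5000, sep_bp=25_000, group=group)
        )
        kinds.append(k)
    a = rng.uniform(0.5, 2.0, n_obs)
    b = rng.uniform(0.2, 1.0, n_obs)
    P_axis = np.array([30.0, 60.0, 90.0, 120.0])
    C_axis = np.array([30.0, 50.0, 70.0, 90.0])

    def predict(P, C, k):
        # distances ~ (P^(1-nu)/C^nu) s^nu flavored response plus a telomere-
        # like term that breaks the (P, C) degeneracy on part of the schema
        base = 300.0 * a[k] * (P**0.5) / (C**0.5)
        breaker = 40.0 * b[k] * (P / 60.0) ** (0.2 if k % 3 else 1.2)
        return base + breaker

    vals = np.zeros((P_axis.size, C_axis.size, 1, 1, n_obs))
    for i, P in enumerate(P_axis):
        for j, C in enumerate(C_axis):
            for k in range(n_obs):
                vals[i, j, 0, 0, k] = predict(P, C, k)
    return ModelGrid(
        schema=tuple(specs),
        axes={"P": P_axis, "C": C_axis, "W": np.array([30.0]), "L": np.array([140.0])},
        node_values=vals,
        node_spread=np.zeros_like(vals),
    )
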