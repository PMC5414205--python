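"""File formats: trajectories (HDF5), XYZ export, genome/observable tables,
BED-like chain annotations, and run configuration."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import yaml

from .genome import (
    GenomeSpec,
    NucleusGeometry,
    ParameterPoint,
    discretize_genome,
    load_genome_spec,
    yeast_genome,
)
from .simulate import ForceField, System, Trajectory, build_system

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "export_xyz",
    "chain_annotations_bed",
    "load_config",
]


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Chunked HDF5 container with enough metadata to rebuild the system."""
    system = traj.system
    with h5py.File(path, "w") as fh:
        fh.create_dataset("positions", data=traj.positions, chunks=True, compression="gzip")
        fh.create_dataset("times", data=traj.times)
        fh.attrs["P"] = system.params.P
        fh.attrs["C"] = system.params.C
        fh.attrs["W"] = system.params.W
        fh.attrs["L"] = system.params.L
        for key in ("seed", "dt", "sample_every", "equilibration_steps", "n_steps"):
            if key in traj.metadata:
                fh.attrs[key] = traj.metadata[key]
        if system.geometry is not None:
            g = system.geometry
            fh.attrs["R_N"] = g.R_N
            fh.attrs["W_rDNA"] = g.W_rDNA
            fh.attrs["n_rdna_beads"] = g.n_rdna_beads
            fh.attrs["spb_position"] = list(g.spb_position)
        chains = fh.create_group("chains")
        for c, chain in enumerate(system.chains):
            grp = chains.create_group(f"{c:03d}")
            grp.attrs["chromosome"] = chain.chromosome
            grp.attrs["centromere_bead_index"] = chain.centromere_bead_index
            grp.attrs["bp_per_bead"] = chain.bp_per_bead
            if chain.rdna_bead_range is not None:
                grp.attrs["rdna_bead_range"] = list(chain.rdna_bead_range)
            grp.create_dataset("bead_diameters", data=np.asarray(chain.bead_diameters))
            grp.create_dataset("bead_bp_edges", data=np.asarray(chain.bead_bp_edges))


def read_trajectory(path: str | Path, force_field: Optional[ForceField] = None) -> Trajectory:
    from .genome import BeadChain

    with h5py.File(path, "r") as fh:
        positions = fh["positions"][...]
        times = fh["times"][...]
        params = ParameterPoint(fh.attrs["P"], fh.attrs["C"], fh.attrs["W"], fh.attrs["L"])
        geometry = None
        if "R_N" in fh.attrs:
            geometry = NucleusGeometry(
                R_N=float(fh.attrs["R_N"]),
                W_rDNA=float(fh.attrs["W_rDNA"]),
                n_rdna_beads=int(fh.attrs["n_rdna_beads"]),
                spb_position=tuple(fh.attrs["spb_position"]),
            )
        chains = []
        for key in sorted(fh["chains"]):
            grp = fh["chains"][key]
            diam = grp["bead_diameters"][...]
            edges = grp["bead_bp_edges"][...]
            n = diam.size
            chains.append(
                BeadChain(
                    chromosome=str(grp.attrs["chromosome"]),
                    bead_count=n,
                    bead_diameters=diam.tolist(),
                    bp_per_bead=float(grp.attrs["bp_per_bead"]),
                    centromere_bead_index=int(grp.attrs["centromere_bead_index"]),
                    telomere_bead_indices=(0, n - 1),
                    rdna_bead_range=tuple(grp.attrs["rdna_bead_range"])
                    if "rdna_bead_range" in grp.attrs
                    else None,
                    bead_bp_edges=edges.tolist(),
                )
            )
        meta = {k: fh.attrs[k] for k in fh.attrs}
    system = build_system(chains, geometry, params, force_field)
    return Trajectory(times=times, positions=positions, system=system, metadata=dict(meta))


def export_xyz(traj: Trajectory, path: str | Path, stride: int = 1) -> None:
    """Plain XYZ text export for visualization."""
    system = traj.system
    names = []
    for chain in system.chains:
        names.extend([chain.chromosome] * chain.bead_count)
    with open(path, "w") as fh:
        for f in range(0, traj.n_samples, stride):
            fh.write(f"{system.n_beads}\nframe {f}\n")
            for i, (x, y, z) in enumerate(traj.positions[f]):
                fh.write(f"{names[i]} {x:.2f} {y:.2f} {z:.2f}\n")


def chain_annotations_bed(genome: GenomeSpec, params: ParameterPoint,
                          geometry: NucleusGeometry | None = None) -> str:
    """BED-like annotation of centromere, telomere, and rDNA bead intervals."""
    geometry = geometry or NucleusGeometry()
    lines = []
    for chain in discretize_genome(genome, params, geometry):
        edges = chain.bead_bp_edges
        for role, beads in (
            ("telomere", chain.telomere_bead_indices),
            ("centromere", (chain.centromere_bead_index,)),
        ):
            for b in beads:
                lines.append(f"{chain.chromosome}\t{int(edges[b])}\t{int(edges[b + 1])}\t{role}")
        if chain.rdna_bead_range is not None:
            a, b = chain.rdna_bead_range
            lines.append(f"{chain.chromosome}\t{int(edges[a])}\t{int(edges[b])}\trdna")
    return "\n".join(lines) + "\n"


def load_config(path: str | Path) -> dict:
    """YAML run configuration with light validation."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config root must be a mapping")
    errors = []
    params = cfg.get("parameters", {})
    for key in ("P", "C", "W", "L"):
        if key in params and not (isinstance(params[key], (int, float)) and params[key] > 0):
            errors.append(f"parameters.{key}: must be a positive number, got {params[key]!r}")
    sim = cfg.get("simulation", {})
    for key in ("n_steps", "sample_every", "equilibration_steps", "seed"):
        if key in sim and not (isinstance(sim[key], int) and sim[key] >= 0):
            errors.append(f"simulation.{key}: must be a non-negative integer, got {sim[key]!r}")
    if errors:
        raise ValueError("invalid configuration:\n" + "\n".join(errors))
    return cfg
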