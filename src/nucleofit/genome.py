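"""Genome discretization: from genomic coordinates to bead chains.

A chromatin fiber with compaction ``C`` (bp/nm) and width ``W`` (nm) packs
``C*W`` base pairs into each bead of diameter ``W``.  Each chromosome becomes a
chain of touching beads, with the centromere and both telomeres annotated.  The
ribosomal DNA interval on its carrier chromosome is replaced by a fixed number
of enlarged beads whose diameter sets the nucleolar volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

__all__ = [
    "Chromosome",
    "GenomeSpec",
    "ParameterPoint",
    "NucleusGeometry",
    "BeadChain",
    "load_genome_spec",
    "yeast_genome",
    "scaled_genome",
    "rdna_diameter_from_volume_fraction",
    "discretize_chromosome",
    "discretize_genome",
    "locus_to_bead",
    "PRIOR_BOX",
]

#: Flat-prior box for the structural parameters (P nm, C bp/nm, W nm, L nm).
PRIOR_BOX = {"P": (27.0, 252.0), "C": (25.0, 110.0), "W": (30.0, 60.0), "L": (200.0, 400.0)}

#: Number of enlarged beads representing the rDNA array, fixed for all models.
N_RDNA_BEADS = 150


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_bp: int
    centromere_bp: int

    def __post_init__(self):
        if self.length_bp <= 0:
            raise ValueError(f"{self.name}: non-positive length {self.length_bp}")
        if not (0 < self.centromere_bp < self.length_bp):
            raise ValueError(f"{self.name}: centromere {self.centromere_bp} outside (0, {self.length_bp})")


@dataclass(frozen=True)
class GenomeSpec:
    """A genome as an ordered list of chromosomes plus one rDNA interval.

    Coordinates in input tables are 1-based inclusive bp; internally all
    arithmetic is 0-based half-open.
    """

    chromosomes: tuple[Chromosome, ...]
    rdna_chromosome: Optional[str] = None
    rdna_start_bp: Optional[int] = None
    rdna_end_bp: Optional[int] = None

    def __post_init__(self):
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if self.rdna_chromosome is not None:
            chrom = self.chromosome(self.rdna_chromosome)
            if not (1 <= self.rdna_start_bp < self.rdna_end_bp <= chrom.length_bp):
                raise ValueError("rDNA interval outside its chromosome")

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"unknown chromosome {name!r}")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def total_bp(self) -> int:
        return sum(c.length_bp for c in self.chromosomes)

    def rdna_interval_for(self, name: str) -> Optional[tuple[int, int]]:
        """0-based half-open rDNA interval if ``name`` carries it, else None."""
        if self.rdna_chromosome == name:
            return (self.rdna_start_bp - 1, self.rdna_end_bp)
        return None


@dataclass(frozen=True)
class ParameterPoint:
    """Structural parameter vector: persistence length P (nm), compaction C
    (bp/nm), fiber width W (nm), microtubule rest length L (nm)."""

    P: float
    C: float
    W: float
    L: float

    def __post_init__(self):
        for name in ("P", "C", "W", "L"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def bp_per_bead(self) -> float:
        return self.C * self.W

    def in_prior_box(self, box: dict | None = None) -> bool:
        box = PRIOR_BOX if box is None else box
        return all(lo <= getattr(self, k) <= hi for k, (lo, hi) in box.items())

    def as_array(self):
        import numpy as np

        return np.array([self.P, self.C, self.W, self.L])


@dataclass(frozen=True)
class NucleusGeometry:
    """Nuclear sphere of radius R_N with the SPB fixed on the envelope and
    the rDNA bead diameter W_rDNA controlling nucleolar volume."""

    R_N: float = 1000.0
    W_rDNA: float = 194.0
    n_rdna_beads: int = N_RDNA_BEADS
    spb_position: tuple[float, float, float] = None  # defaults to (0, 0, -R_N)

    def __post_init__(self):
        if self.R_N <= 0:
            raise ValueError("R_N must be positive")
        if self.spb_position is None:
            object.__setattr__(self, "spb_position", (0.0, 0.0, -self.R_N))
        r = math.dist(self.spb_position, (0, 0, 0))
        if abs(r - self.R_N) > 1e-6 * self.R_N:
            raise ValueError("SPB must lie on the nuclear envelope")


def nucleosomes_per_turn(C: float, repeat_bp: float = 167.0, turn_nm: float = 11.0) -> float:
    """Nucleosomes per ``turn_nm`` of fiber implied by a compaction C (bp/nm).

    With the yeast nucleosome repeat length of 167 bp, a compaction of
    61 bp/nm corresponds to about four nucleosomes per 11 nm — far looser
    than a classical 30 nm fiber (~11 per 11 nm) and denser than an extended
    beads-on-a-string fiber (~1 per 11 nm).
    """
    if C <= 0 or repeat_bp <= 0 or turn_nm <= 0:
        raise ValueError("inputs must be positive")
    return C * turn_nm / repeat_bp


def mixture_genome_fractions(
    dense_nucs_per_turn: float = 6.0, loose_nucs_per_turn: float = 1.0
) -> tuple[float, float]:
    """Genome fractions of a two-state fiber mixing equal *linear* lengths.

    If half of the fiber's contour is a dense structure (e.g. 6 nucleosomes
    per 11 nm) and half a loose one (1 per 11 nm), the dense state carries
    dense/(dense+loose) of the genome — 6/7 ~ 86% against 1/7 ~ 14%.
    """
    if dense_nucs_per_turn <= 0 or loose_nucs_per_turn <= 0:
        raise ValueError("packing densities must be positive")
    total = dense_nucs_per_turn + loose_nucs_per_turn
    return dense_nucs_per_turn / total, loose_nucs_per_turn / total


def rdna_diameter_from_volume_fraction(V: float, R_N: float, n_beads: int) -> float:
    """Bead diameter making ``n_beads`` spheres occupy net fraction ``V`` of
    the nuclear sphere of radius ``R_N``.

    n * (pi/6) d^3 = V * (4/3) pi R_N^3  =>  d = 2 R_N (V / n)^(1/3)
    """
    if not (0 < V < 1):
        raise ValueError("V must be in (0, 1)")
    if R_N <= 0 or n_beads < 1:
        raise ValueError("R_N must be positive and n_beads >= 1")
    return 2.0 * R_N * (V / n_beads) ** (1.0 / 3.0)


@dataclass
class BeadChain:
    """One chromosome as a bead chain.

    ``bead_bp_edges`` holds the 0-based bp boundary of every bead (length
    ``bead_count + 1``), so bead ``i`` tiles ``[edges[i], edges[i+1])``.
    """

    chromosome: str
    bead_count: int
    bead_diameters: "list[float]"
    bp_per_bead: float
    centromere_bead_index: int
    telomere_bead_indices: tuple[int, int]
    rdna_bead_range: Optional[tuple[int, int]] = None  # half-open bead indices
    bead_bp_edges: Sequence[float] = field(default_factory=list)

    def bead_at_bp(self, position_bp: int) -> int:
        """Nearest-bead mapping of a 0-based bp position."""
        edges = self.bead_bp_edges
        if not (0 <= position_bp <= edges[-1]):
            raise ValueError(f"{self.chromosome}: position {position_bp} out of range")
        # binary search over the tile edges
        import bisect

        i = bisect.bisect_right(edges, position_bp) - 1
        return min(i, self.bead_count - 1)


def discretize_chromosome(
    length_bp: int,
    parameter_point: ParameterPoint,
    centromere_bp: int | None = None,
    rdna_interval: tuple[int, int] | None = None,
    geometry: NucleusGeometry | None = None,
    name: str = "chr",
) -> BeadChain:
    """Tile a chromosome into beads of ``C*W`` bp each.

    Bead counts use the ceiling so no sequence is dropped; the terminal
    partial bead keeps the full diameter W.  If ``rdna_interval`` (0-based
    half-open bp) is given, that stretch is replaced by exactly
    ``geometry.n_rdna_beads`` beads of diameter ``geometry.W_rDNA``.
    """
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    bp_per_bead = parameter_point.bp_per_bead
    W = parameter_point.W

    if rdna_interval is None:
        n = math.ceil(length_bp / bp_per_bead)
        edges = [min(i * bp_per_bead, length_bp) for i in range(n)] + [float(length_bp)]
        diameters = [W] * n
        rdna_range = None
    else:
        if geometry is None:
            geometry = NucleusGeometry()
        a, b = rdna_interval
        if not (0 <= a < b <= length_bp):
            raise ValueError("rDNA interval outside chromosome")
        n_left = math.ceil(a / bp_per_bead) if a > 0 else 0
        n_rdna = geometry.n_rdna_beads
        n_right = math.ceil((length_bp - b) / bp_per_bead) if b < length_bp else 0
        n = n_left + n_rdna + n_right
        edges = [min(i * bp_per_bead, float(a)) for i in range(n_left)]
        rdna_bp = (b - a) / n_rdna
        edges += [a + i * rdna_bp for i in range(n_rdna)]
        edges += [min(b + i * bp_per_bead, float(length_bp)) for i in range(n_right)]
        edges += [float(length_bp)]
        diameters = [W] * n_left + [geometry.W_rDNA] * n_rdna + [W] * n_right
        rdna_range = (n_left, n_left + n_rdna)

    chain = BeadChain(
        chromosome=name,
        bead_count=n,
        bead_diameters=diameters,
        bp_per_bead=bp_per_bead,
        centromere_bead_index=0,
        telomere_bead_indices=(0, n - 1),
        rdna_bead_range=rdna_range,
        bead_bp_edges=edges,
    )
    if centromere_bp is not None:
        chain.centromere_bead_index = chain.bead_at_bp(centromere_bp - 1)
    return chain


def discretize_genome(
    genome: GenomeSpec, parameter_point: ParameterPoint, geometry: NucleusGeometry | None = None
) -> list[BeadChain]:
    """Discretize every chromosome of a genome."""
    if geometry is None:
        geometry = NucleusGeometry()
    chains = []
    for chrom in genome.chromosomes:
        chains.append(
            discretize_chromosome(
                chrom.length_bp,
                parameter_point,
                centromere_bp=chrom.centromere_bp,
                rdna_interval=genome.rdna_interval_for(chrom.name),
                geometry=geometry,
                name=chrom.name,
            )
        )
    return chains


def locus_to_bead(
    genome: GenomeSpec, chains: Sequence[BeadChain], chromosome: str, position_bp: int
) -> tuple[BeadChain, int]:
    """Map a 0-based bp offset to (chain, bead index) under the current tiling.

    Input tables use 1-based inclusive coordinates; the I/O layer subtracts 1
    before calling this.
    """
    genome.chromosome(chromosome)  # raises KeyError if unknown
    for chain in chains:
        if chain.chromosome == chromosome:
            return chain, chain.bead_at_bp(position_bp)
    raise KeyError(f"no chain for chromosome {chromosome!r}")


# ---------------------------------------------------------------------------
# Packaged genome specifications


def load_genome_spec(path: str | Path) -> GenomeSpec:
    """Read a genome spec table (columns name, length_bp, centromere_bp;
    separate ``rdna`` line with chromosome, start_bp, end_bp)."""
    chromosomes = []
    rdna = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if parts[0] == "rdna":
            rdna = (parts[1], int(parts[2]), int(parts[3]))
        else:
            chromosomes.append(Chromosome(parts[0], int(parts[1]), int(parts[2])))
    kwargs = {}
    if rdna is not None:
        kwargs = dict(rdna_chromosome=rdna[0], rdna_start_bp=rdna[1], rdna_end_bp=rdna[2])
    return GenomeSpec(tuple(chromosomes), **kwargs)


def yeast_genome() -> GenomeSpec:
    """The packaged 16-chromosome S. cerevisiae genome (sacCer3 lengths)."""
    with resources.as_file(resources.files("nucleofit.data") / "sc_genome.tsv") as p:
        spec = load_genome_spec(p)
    assert len(spec.chromosomes) == 16
    return spec


def scaled_genome() -> GenomeSpec:
    """Reduced 3-chromosome genome for desk-scale validation runs.

    Chromosome lengths are one fifth of yeast chr1, chr6 and chr12-like
    lengths; the third chromosome carries a proportionally scaled rDNA
    interval.
    """
    return GenomeSpec(
        (
            Chromosome("chrA", 46000, 30300),
            Chromosome("chrB", 162000, 29700),
            Chromosome("chrC", 306000, 30200),
        ),
        rdna_chromosome="chrC",
        rdna_start_bp=90000,
        rdna_end_bp=94000,
    )
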