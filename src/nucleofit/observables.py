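"""Summary statistics computed from simulated trajectories.

Each observable mirrors a measurement class used for nuclear-architecture
data: distance statistics between locus pairs (3D, or 2D after projection),
angles to the nucleolar axis, Hi-C-style contact-frequency summaries, and
locus mean-squared displacements.  Observables are addressed by an
:class:`ObservableSpec`, so the same schema describes experimental tables and
model predictions.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import gaussian_kde

from .simulate import System, Trajectory

__all__ = [
    "ObservableSpec",
    "ObservableSet",
    "ContactMap",
    "SPB",
    "NUCLEOLUS",
    "DISTANCE_CLASSES",
    "CONTACT_CLASSES",
    "pairwise_distance_stats",
    "angle_to_nucleolar_axis",
    "bead_contact_frequencies",
    "contact_map",
    "hic_summaries",
    "msd",
    "fit_time_scale",
    "compute_observables",
]

#: Special locus tokens: the spindle pole body and the nucleolar centroid.
SPB = "SPB"
NUCLEOLUS = "NUCLEOLUS"

DISTANCE_CLASSES = {
    "median_3d_distance",
    "median_2d_distance",
    "mean_3d_distance",
    "mode_3d_distance",
}
CONTACT_CLASSES = {
    "contact_summary_intra",
    "contact_summary_inter",
    "contact_vs_s_genomewide",
    "contact_vs_s_centromeric",
}
ALL_CLASSES = DISTANCE_CLASSES | CONTACT_CLASSES | {"median_angle"}


@dataclass(frozen=True)
class ObservableSpec:
    """Address of one scalar observable.

    ``chrom_a``/``bp_a`` (and optionally ``chrom_b``/``bp_b``) locate the loci
    involved; contact classes use ``chrom_a`` as the chromosome and ``sep_bp``
    as the genomic-separation bin center.  ``group`` tags the data pool the
    measurement belongs to (live imaging, fixed imaging, or one of the two
    Hi-C studies) for the nuisance variance model.
    """

    id: str
    cls: str
    chrom_a: str = ""
    bp_a: int = 0
    chrom_b: str = ""
    bp_b: int = 0
    sep_bp: int = 0
    group: str = "live_imaging"

    def __post_init__(self):
        if self.cls not in ALL_CLASSES:
            raise ValueError(f"unknown observable class {self.cls!r}")


@dataclass
class ObservableSet:
    """Ordered set of observable values with sampling standard errors."""

    specs: tuple[ObservableSpec, ...]
    values: np.ndarray
    stderr: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.stderr is None:
            self.stderr = np.zeros_like(self.values)
        self.stderr = np.asarray(self.stderr, float)
        if not (len(self.specs) == self.values.size == self.stderr.size):
            raise ValueError("specs/values/stderr length mismatch")

    def __len__(self):
        return len(self.specs)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.specs]

    def value(self, obs_id: str) -> float:
        return float(self.values[self.ids.index(obs_id)])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, v, e in zip(self.specs, self.values, self.stderr):
            rows.append(
                dict(
                    id=s.id, cls=s.cls, chrom_a=s.chrom_a, bp_a=s.bp_a, chrom_b=s.chrom_b,
                    bp_b=s.bp_b, sep_bp=s.sep_bp, group=s.group, value=v, stderr=e,
                )
            )
        return pd.DataFrame(rows)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ObservableSet":
        specs = tuple(
            ObservableSpec(
                id=str(r.id), cls=str(r.cls), chrom_a=str(r.chrom_a) if not pd.isna(r.chrom_a) else "",
                bp_a=int(r.bp_a), chrom_b=str(r.chrom_b) if not pd.isna(r.chrom_b) else "",
                bp_b=int(r.bp_b), sep_bp=int(r.sep_bp), group=str(r.group),
            )
            for r in df.itertuples()
        )
        err = df["stderr"].to_numpy() if "stderr" in df else None
        return cls(specs, df["value"].to_numpy(), err)

    @classmethod
    def read(cls, path: str | Path) -> "ObservableSet":
        return cls.from_frame(pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[]))


@dataclass
class ContactMap:
    """Symmetric contact-frequency matrix over genomic bins.

    ``bins`` is a DataFrame with columns chrom, start, end (0-based
    half-open); ``matrix`` is symmetric with frequencies in [0, 1].
    """

    bins: pd.DataFrame
    matrix: np.ndarray
    bin_size_bp: int

    def __post_init__(self):
        m = np.asarray(self.matrix, float)
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.bins):
            raise ValueError("matrix/bins shape mismatch")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("contact matrix must be symmetric")
        self.matrix = m

    def write_dense(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#chrom\tstart\tend\n")
            for r in self.bins.itertuples():
                fh.write(f"#{r.chrom}\t{r.start}\t{r.end}\n")
            np.savetxt(fh, self.matrix, fmt="%.6g")

    def write_triplets(self, path: str | Path) -> None:
        i, j = np.nonzero(np.triu(self.matrix))
        pd.DataFrame({"bin_i": i, "bin_j": j, "frequency": self.matrix[i, j]}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def read_dense(cls, path: str | Path) -> "ContactMap":
        bins = []
        rows = []
        for line in Path(path).read_text().splitlines():
            if line.startswith("#chrom"):
                continue
            if line.startswith("#"):
                chrom, start, end = line[1:].split("\t")
                bins.append(dict(chrom=chrom, start=int(start), end=int(end)))
            elif line.strip():
                rows.append([float(x) for x in line.split()])
        bins = pd.DataFrame(bins)
        size = int((bins["end"] - bins["start"]).max()) if len(bins) else 0
        return cls(bins=bins, matrix=np.array(rows), bin_size_bp=size)

    @classmethod
    def read_triplets(cls, path: str | Path, bins: pd.DataFrame, bin_size_bp: int) -> "ContactMap":
        df = pd.read_csv(path, sep="\t")
        n = len(bins)
        mat = np.zeros((n, n))
        mat[df["bin_i"], df["bin_j"]] = df["frequency"]
        mat = np.maximum(mat, mat.T)
        return cls(bins=bins, matrix=mat, bin_size_bp=bin_size_bp)


# ---------------------------------------------------------------------------
# locus resolution


def _chain_index(system: System, chromosome: str) -> int:
    for c, ch in enumerate(system.chains):
        if ch.chromosome == chromosome:
            return c
    raise KeyError(f"no chain for chromosome {chromosome!r}")


def locus_positions(traj: Trajectory, chromosome: str, bp: int = 0) -> np.ndarray:
    """Per-frame position of a locus: (n_samples, 3) in nm.

    ``SPB`` resolves to the fixed spindle-pole-body anchor and ``NUCLEOLUS``
    to the per-frame centroid of the rDNA beads.
    """
    system = traj.system
    if chromosome == SPB:
        if system.geometry is None:
            raise ValueError("SPB undefined for unconfined systems")
        return np.broadcast_to(np.asarray(system.geometry.spb_position), (traj.n_samples, 3))
    if chromosome == NUCLEOLUS:
        if system.rdna_beads.size == 0:
            raise ValueError("no rDNA beads in this system")
        return traj.positions[:, system.rdna_beads, :].mean(axis=1)
    c = _chain_index(system, chromosome)
    chain = system.chains[c]
    bead = chain.bead_at_bp(bp)
    return traj.positions[:, system.global_bead(c, bead), :]


def _project_2d(disp: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Norm of displacements projected on a fresh uniformly random plane per
    frame (imaging-axis isotropy)."""
    axes = rng.standard_normal(disp.shape)
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    along = np.einsum("ij,ij->i", disp, axes)
    d2 = np.einsum("ij,ij->i", disp, disp) - along**2
    return np.sqrt(np.maximum(d2, 0.0))


def _mode_estimate(samples: np.ndarray) -> float:
    """Peak of a Gaussian-kernel density with Silverman bandwidth."""
    if np.ptp(samples) < 1e-12:
        return float(samples[0])
    kde = gaussian_kde(samples, bw_method="silverman")
    grid = np.linspace(samples.min(), samples.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def _block_stderr(per_frame: np.ndarray, statistic, n_blocks: int = 10) -> float:
    blocks = np.array_split(per_frame, n_blocks)
    vals = np.array([statistic(b) for b in blocks if b.size])
    return float(vals.std(ddof=1) / np.sqrt(len(vals)))


def pairwise_distance_stats(
    traj: Trajectory,
    locus_a: tuple[str, int],
    locus_b: tuple[str, int],
    statistic: str = "median",
    projection: str = "3d",
    seed: int = 0,
    return_stderr: bool = False,
):
    """Statistic of per-frame Euclidean distances between two loci (nm).

    2D projection drops one axis after a fresh uniformly random rotation per
    frame.  The mode uses a kernel-smoothed histogram peak and needs at least
    200 frames; mean/median need at least 30.
    """
    min_frames = 200 if statistic == "mode" else 30
    if traj.n_samples < min_frames:
        raise ValueError(f"{statistic} needs >= {min_frames} frames, have {traj.n_samples}")
    pa = locus_positions(traj, *locus_a)
    pb = locus_positions(traj, *locus_b)
    disp = pa - pb
    if projection == "2d":
        rng = np.random.default_rng(seed)
        d = _project_2d(disp, rng)
    elif projection == "3d":
        d = np.linalg.norm(disp, axis=1)
    else:
        raise ValueError("projection must be '2d' or '3d'")
    stat_fn = {"mean": np.mean, "median": np.median, "mode": _mode_estimate}[statistic]
    val = float(stat_fn(d))
    if return_stderr:
        return val, _block_stderr(d, stat_fn)
    return val


def angle_to_nucleolar_axis(
    traj: Trajectory, locus: tuple[str, int], return_stderr: bool = False
):
    """Median over frames of the angle (degrees) at the nuclear center between
    the locus and the nucleolar centroid."""
    p = locus_positions(traj, *locus)
    c = locus_positions(traj, NUCLEOLUS)
    np_norm = np.linalg.norm
    denom = np_norm(p, axis=1) * np_norm(c, axis=1)
    if np.any(denom < 1e-9):
        raise ValueError("degenerate zero-length vector in angle computation")
    cosang = np.clip(np.einsum("ij,ij->i", p, c) / denom, -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    if return_stderr:
        return float(np.median(ang)), _block_stderr(ang, np.median)
    return float(np.median(ang))


# ---------------------------------------------------------------------------
# contacts


def default_contact_cutoff(system: System) -> float:
    """Surface-proximity cutoff: twice the fiber width."""
    return 2.0 * system.params.W


def bead_contact_frequencies(traj: Trajectory, cutoff_nm: float | None = None) -> np.ndarray:
    """Fraction of frames in which each bead pair is closer than the cutoff."""
    if cutoff_nm is None:
        cutoff_nm = default_contact_cutoff(traj.system)
    if cutoff_nm <= 0:
        raise ValueError("cutoff must be positive")
    n = traj.positions.shape[1]
    acc = np.zeros((n, n))
    for frame in traj.positions:
        acc += squareform(pdist(frame) < cutoff_nm).astype(float)
    acc /= traj.n_samples
    np.fill_diagonal(acc, 1.0)
    return acc


def _bead_bins(system: System) -> pd.DataFrame:
    rows = []
    for c, chain in enumerate(system.chains):
        edges = np.asarray(chain.bead_bp_edges)
        for b in range(chain.bead_count):
            rows.append(dict(chrom=chain.chromosome, start=int(edges[b]), end=int(edges[b + 1])))
    return pd.DataFrame(rows)


def contact_map(
    traj: Trajectory, bin_size_bp: int, contact_cutoff_nm: float | None = None
) -> ContactMap:
    """Bead contacts aggregated to fixed genomic bins (mean frequency of the
    bead pairs mapping to each bin pair)."""
    system = traj.system
    max_tile = max(ch.bp_per_bead for ch in system.chains)
    if bin_size_bp < max_tile:
        raise ValueError(f"bin size {bin_size_bp} bp below the {max_tile:.0f} bp/bead tiling")
    freq = bead_contact_frequencies(traj, contact_cutoff_nm)
    bead_bins = _bead_bins(system)

    rows = []
    bead_to_bin = np.zeros(len(bead_bins), dtype=int)
    k = 0
    for chrom, sub in bead_bins.groupby("chrom", sort=False):
        length = sub["end"].max()
        n_bins = int(np.ceil(length / bin_size_bp))
        for b in range(n_bins):
            rows.append(dict(chrom=chrom, start=b * bin_size_bp, end=min((b + 1) * bin_size_bp, length)))
        mid = (sub["start"].to_numpy() + sub["end"].to_numpy()) / 2.0
        bead_to_bin[sub.index.to_numpy()] = k + np.minimum(
            (mid // bin_size_bp).astype(int), n_bins - 1
        )
        k += n_bins
    bins = pd.DataFrame(rows)
    nb = len(bins)
    mat = np.zeros((nb, nb))
    counts = np.zeros((nb, nb))
    np.add.at(mat, (bead_to_bin[:, None].repeat(len(bead_bins), 1), bead_to_bin[None, :].repeat(len(bead_bins), 0)), freq)
    np.add.at(counts, (bead_to_bin[:, None].repeat(len(bead_bins), 1), bead_to_bin[None, :].repeat(len(bead_bins), 0)), 1.0)
    with np.errstate(invalid="ignore"):
        mat = np.where(counts > 0, mat / np.maximum(counts, 1), 0.0)
    mat = 0.5 * (mat + mat.T)
    return ContactMap(bins=bins, matrix=mat, bin_size_bp=bin_size_bp)


#: Lower edges of the 12 genomic-separation bins (5 kb wide, spanning
#: 25-85 kb) for contact-vs-distance profiles.
HIC_SEP_BINS = tuple(range(25_000, 85_000, 5_000))


def hic_summaries(
    freq: np.ndarray, system: System, group: str = "hic_A", sep_bins: Sequence[int] = HIC_SEP_BINS
) -> ObservableSet:
    """Contact-frequency summary schema from a bead-resolution frequency
    matrix: per-chromosome intra and inter means, plus intrachromosomal
    contact-vs-separation profiles genome-wide and relative to the centromere.
    """
    specs, values = [], []
    chains = system.chains
    # per-chromosome intra / inter means
    for c, chain in enumerate(chains):
        sl = system.chain_slice(c)
        sub = freq[sl, sl]
        iu = np.triu_indices(chain.bead_count, k=1)
        intra = float(sub[iu].mean()) if iu[0].size else 0.0
        mask = np.ones(freq.shape[0], bool)
        mask[sl] = False
        inter = float(freq[sl, :][:, mask].mean())
        specs.append(
            ObservableSpec(id=f"{group}:intra:{chain.chromosome}", cls="contact_summary_intra",
                           chrom_a=chain.chromosome, group=group)
        )
        values.append(intra)
        specs.append(
            ObservableSpec(id=f"{group}:inter:{chain.chromosome}", cls="contact_summary_inter",
                           chrom_a=chain.chromosome, group=group)
        )
        values.append(inter)
    # order: all intra then all inter (schema convention)
    specs = specs[0::2] + specs[1::2]
    values = values[0::2] + values[1::2]

    # genomic-separation profiles
    mids, cen_dist, chrom_of = [], [], []
    for c, chain in enumerate(chains):
        edges = np.asarray(chain.bead_bp_edges)
        m = (edges[:-1] + edges[1:]) / 2.0
        mids.append(m)
        chrom_of.append(np.full(chain.bead_count, c))
    mids = np.concatenate(mids)
    chrom_of = np.concatenate(chrom_of)

    same = chrom_of[:, None] == chrom_of[None, :]
    sep = np.abs(mids[:, None] - mids[None, :])
    iu = np.triu_indices(freq.shape[0], k=1)
    same_u, sep_u, f_u = same[iu], sep[iu], freq[iu]
    bin_width = 5_000
    for s in sep_bins:
        m = same_u & (sep_u >= s) & (sep_u < s + bin_width)
        val = float(f_u[m].mean()) if m.any() else 0.0
        specs.append(
            ObservableSpec(id=f"{group}:vs_s:{s}", cls="contact_vs_s_genomewide", sep_bp=s, group=group)
        )
        values.append(val)
    # relative to the centromere: contacts of the centromeric bead with loci
    # at genomic separation s, averaged over chromosomes
    for s in sep_bins:
        acc = []
        for c, chain in enumerate(chains):
            cen = system.global_bead(c, chain.centromere_bead_index)
            sl = system.chain_slice(c)
            d = np.abs(mids[sl] - mids[cen])
            m = (d >= s) & (d < s + bin_width)
            if m.any():
                acc.append(freq[cen, sl.start:sl.stop][m].mean())
        val = float(np.mean(acc)) if acc else 0.0
        specs.append(
            ObservableSpec(id=f"{group}:vs_cen:{s}", cls="contact_vs_s_centromeric", sep_bp=s, group=group)
        )
        values.append(val)
    return ObservableSet(tuple(specs), np.array(values))


# ---------------------------------------------------------------------------
# dynamics


def msd(traj: Trajectory, locus: tuple[str, int], lags: Sequence[int]) -> np.ndarray:
    """Time-averaged mean-squared displacement (nm^2) of a locus bead at the
    given sample-index lags."""
    p = locus_positions(traj, *locus)
    out = np.empty(len(lags))
    for k, lag in enumerate(lags):
        if lag >= traj.n_samples:
            raise ValueError(f"lag {lag} exceeds trajectory span {traj.n_samples}")
        if lag == 0:
            out[k] = 0.0
            continue
        d = p[lag:] - p[:-lag]
        out[k] = np.einsum("ij,ij->i", d, d).mean()
    return out


def fit_time_scale(
    t_sim: np.ndarray, msd_sim: np.ndarray, t_exp: np.ndarray, msd_exp: np.ndarray
) -> float:
    """Multiplicative time-axis scale a (physical seconds per simulation time
    unit) aligning the simulated MSD curve to the experimental one.

    Least squares on log MSD over the overlapping lag range, with the
    simulated curve interpolated on a log-log scale.
    """
    t_sim, msd_sim = np.asarray(t_sim, float), np.asarray(msd_sim, float)
    t_exp, msd_exp = np.asarray(t_exp, float), np.asarray(msd_exp, float)

    def cost(log_a):
        a = np.exp(log_a)
        ts = t_exp / a
        inside = (ts >= t_sim.min()) & (ts <= t_sim.max())
        if inside.sum() < 2:
            return 1e12 + log_a**2
        pred = np.interp(np.log(ts[inside]), np.log(t_sim), np.log(msd_sim))
        return float(np.mean((pred - np.log(msd_exp[inside])) ** 2))

    from scipy.optimize import minimize_scalar

    res = minimize_scalar(cost, bounds=(-20, 20), method="bounded", options={"xatol": 1e-8})
    return float(np.exp(res.x))


# ---------------------------------------------------------------------------
# schema evaluation


def compute_observables(
    traj: Trajectory,
    schema: Sequence[ObservableSpec],
    contact_cutoff_nm: float | None = None,
    seed: int = 0,
) -> ObservableSet:
    """Evaluate a whole observable schema on one trajectory.

    Unresolvable loci are collected and reported together.
    """
    system = traj.system
    need_contacts = any(s.cls in CONTACT_CLASSES for s in schema)
    contact_sets: dict[str, ObservableSet] = {}
    if need_contacts:
        freq = bead_contact_frequencies(traj, contact_cutoff_nm)
        for group in {s.group for s in schema if s.cls in CONTACT_CLASSES}:
            contact_sets[group] = hic_summaries(freq, system, group=group)

    values = np.empty(len(schema))
    errs = np.zeros(len(schema))
    errors = []
    for k, spec in enumerate(schema):
        try:
            if spec.cls in DISTANCE_CLASSES:
                stat = spec.cls.split("_")[0]
                proj = "2d" if "2d" in spec.cls else "3d"
                values[k], errs[k] = pairwise_distance_stats(
                    traj,
                    (spec.chrom_a, spec.bp_a),
                    (spec.chrom_b, spec.bp_b),
                    statistic=stat,
                    projection=proj,
                    seed=seed + zlib.crc32(spec.id.encode()) % 2**16,
                    return_stderr=True,
                )
            elif spec.cls == "median_angle":
                values[k], errs[k] = angle_to_nucleolar_axis(
                    traj, (spec.chrom_a, spec.bp_a), return_stderr=True
                )
            else:
                cset = contact_sets[spec.group]
                # match by class and address within the group's summary set
                match = [
                    i
                    for i, s in enumerate(cset.specs)
                    if s.cls == spec.cls and s.chrom_a == spec.chrom_a and s.sep_bp == spec.sep_bp
                ]
                if not match:
                    raise KeyError(spec.id)
                values[k] = cset.values[match[0]]
        except (KeyError, ValueError) as exc:
            errors.append(f"{spec.id}: {exc}")
            values[k] = np.nan
    if errors:
        raise ValueError("unresolvable observables:\n" + "\n".join(errors))
    return ObservableSet(tuple(schema), values, errs)
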