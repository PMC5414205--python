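# Methods

## The model

`nucleofit` treats each of the 16 budding-yeast chromosomes as a coarse-grained
bead-spring polymer confined to a spherical nucleus. A chromatin fiber of
compaction `C` (bp/nm) and width `W` (nm) packs `C·W` base pairs into each
bead of diameter `W`; bead counts per chromosome follow from genomic length by
a ceiling division (no sequence is dropped; the terminal partial bead keeps
diameter `W`). The structural parameter vector is `Π = (P, C, W, L)`:
persistence length `P` (nm), compaction `C` (bp/nm), fiber width `W` (nm), and
the rest length `L` (nm) of the centromere–spindle-pole-body (SPB) tether.

Potentials (all energies in units of kT):

* **Bonds** — a finitely extensible spring centred at the rest length
  `r0 = (d_i + d_j)/2` and diverging at `±0.5 r0`
  (`U = −½ k Δm² ln(1 − ((r−r0)/Δm)²)`, `k = 2 kT/nm²`, `Δm = 0.5 r0`).
  Together with the repulsive core this prevents chain crossing.
* **Bending** — a discrete worm-like-chain penalty `k_b (1 − cos θ)` per bead
  triplet. The leading-order constant is `k_b = P/b`; the force field uses the
  exact inversion of the mean joint cosine, `coth(k_b) − 1/k_b = exp(−b/P)`,
  so that a simulated chain realizes the requested `P` even when `b/P` is not
  small. Both forms are exposed by `bending_constant_from_P`.
* **Excluded volume** — a purely repulsive truncated-and-shifted 12-6 (WCA)
  core with per-pair contact distance `(d_i + d_j)/2` and `ε = 1 kT`, acting
  between all bead pairs through a Verlet neighbor list.
* **Confinement** — a harmonic wall (`k = 1 kT/nm²`) on the excess of a
  bead's radius beyond `R_N − d_i/2`, with `R_N = 1000 nm`.
* **SPB tether** — a harmonic spring (`k = 0.5 kT/nm²`) of rest length `L`
  between each centromeric bead and the SPB, fixed at `(0, 0, −R_N)` (any
  envelope point is equivalent by symmetry).
* **Telomere attraction** — a constant outward radial force (`0.2 kT/nm`) on
  the 32 telomeric beads, active only within a 100 nm shell below the
  envelope; deeper beads feel nothing.

The rDNA array on chromosome 12 is represented by 150 enlarged beads of
diameter `W_rDNA`, chosen so that their net volume is a fraction `V` of the
nuclear volume: `W_rDNA = 2 R_N (V / 150)^{1/3}`; `V = 14 %` gives the default
`W_rDNA ≈ 195 nm`. The bead count stays 150 for every parameter point; only
the diameter varies. rDNA beads use the same potential forms with their larger
diameter, and the same `P` over the larger bond length.

## Dynamics

Overdamped (first-order) Langevin integration:
`Δx = (dt/γ) F + √(2 kT dt/γ) ξ`, with `γ = 1` per bead and `kT = 1`.
Equilibrium statistics do not depend on the friction model; locus dynamics are
mapped to physical time afterwards by one fitted multiplicative time scale per
experimental dataset (`fit_time_scale`). The default `dt = 0.04 γ/k_max`
(0.02 time units at the default stiffnesses) was chosen by measuring the
sampled joint-angle distribution against the exact discrete-WLC law: at
`dt = 0.05` the first-order integrator visibly stiffens the chain, at
`dt ≤ 0.02` the bias is below statistical resolution. Divergence (NaN) is
detected at sample boundaries and reported with the step count.

Initial configurations grow each chain as a worm-like-chain walk with joint
angles drawn from the exact equilibrium transfer density — an unconfined
phantom chain therefore *starts* in its equilibrium ensemble. In the nucleus,
centromeres are placed within `2L` of the SPB and both arms grow outward,
redrawing steps that leave the sphere or overlap placed beads (the overlap
tolerance relaxes as retries accumulate; a stuck chain restarts, and an
overfull nucleus raises before any dynamics runs).

A practical note on statistics: global chain observables (end-to-end
distances, low Rouse modes) decorrelate over `~N²` bead time scales, far
longer than a desk-scale run. All equilibrium checks in the test suite
therefore average over *ensembles* of independent chains — phantom chains do
not interact, so many replicas are batched into a single simulation — rather
than trusting time averages of a single trajectory. Confined whole-nucleus
runs use a fixed-duration protocol (identical step counts for every grid node
and replica), so surrogate predictions and synthetic truth data are generated
under exactly the same sampling conditions. An equilibration diagnostic (trend
test on the radius of gyration) is attached to every trajectory and warns,
never errors.

## Observables

Distance statistics (mean / median / kernel-density mode) are computed from
per-frame Euclidean distances; 2D statistics apply a fresh uniformly random
rotation per frame before dropping one axis, which models the unknown imaging
axis and makes projected statistics rotation invariant despite the SPB
anisotropy (a fixed-axis variant is available). Mode estimation uses a
Gaussian kernel with Silverman bandwidth and requires ≥ 200 frames
(mean/median: ≥ 30). Angles are measured at the nuclear center between a locus
and the nucleolar centroid (centroid of the rDNA beads); the locus–nucleolus
distance observable likewise uses the centroid convention.

Contacts are binary per frame (bead-pair distance below a cutoff, default
`2W`, i.e. surface proximity) and averaged over frames. Hi-C summaries emit,
per study, 16 intrachromosomal means + 16 interchromosomal means + 12
genome-wide contact-vs-separation values + 12 centromere-anchored values
(separation bins of 5 kb spanning 25–85 kb); "relative to the centromere" is
implemented as contacts of the centromeric bead with loci at genomic
separation `s`, averaged over chromosomes. Absolute contact frequencies depend
on the cutoff convention, so inference treats their noise scale as a nuisance
parameter per Hi-C study rather than trusting absolute values.

MSDs are time-and-ensemble averaged. The time-scale fit aligns simulated to
experimental MSD curves by least squares on log MSD over the overlapping lag
range with one multiplicative scale per dataset.

## Surrogate grid

Observables are simulated on a lattice of `Π` values (≥ 2 replicas per node,
differing only by seed) and interpolated multilinearly per observable.
Multilinear interpolation is exact at the nodes, continuous across cells, and
monotonicity-preserving within each cell — the right trade-off when node
values carry sampling noise (splines and RBFs can oscillate). Axes need not be
uniform; singleton axes (parameters held fixed) collapse automatically.
Queries outside the lattice hull raise: the sampler is never allowed to
extrapolate the surrogate.

## Inference

For a dataset `D = (Y_1^E … Y_N^E)` the likelihood is independent Gaussian per
measurement with variance `σ_k² = s_k² (ξ_g² + ρ_k²)`, where `s_k` is the
magnitude of the *model prediction* `|Y_k^M(Π)|` (floored at 5 % of the
group's median measurement so near-zero values keep positive variance),
`ξ_g` is one free noise scale per data group, and `ρ_k` is the surrogate's
own relative sampling uncertainty for observable `k` — the relative replica
spread pooled (median) across all lattice nodes, so that finite simulation
sampling is never mistaken for measurement information. Two choices here
were driven by diagnosed failure modes rather than convention. First, σ
scales with the prediction, not the measurement: at high noise a measurement
that noise happens to deflate would otherwise shrink its own error bar and
gain spurious weight, which showed up as rare multi-sigma MAP excursions in
validation (the prediction-scaled form also matches the multiplicative
synthetic-noise generator exactly). Second, `ρ_k` is pooled across nodes
because a per-node spread estimated from few replicas is a
low-degree-of-freedom estimate whose noise distorts the likelihood
landscape. Measurement-scaled and lattice-averaged fixed scales remain
selectable (`make_log_posterior(sigma_scale=...)`); the default was chosen
by comparing all three on repeated synthetic recoveries over two
independently built grids. The groups are
live-cell imaging, fixed-cell imaging, and each Hi-C study separately. This
makes `ξ_g` a relative noise level for distances and contact frequencies
alike. Priors: flat for `Π` over the grid box, half-normal (scale 0.5) for
each `ξ_g`. Sampling uses the affine-invariant stretch-move ensemble sampler
(`emcee`, 32 walkers, 2000–2500 steps by default, 30 % burn-in). Walkers are
seeded near the best lattice node found by a coarse scan, with enough jitter
(15 % of each axis range) to populate ridge-shaped posteriors; an
all-walkers-stuck condition (mean acceptance < 0.05) raises.

Marginals over parameter subsets are Gaussian-KDE smoothed on a rectangular
grid; draws within three bandwidths of a hard prior bound are mirrored across
it before smoothing, so boundary modes are not artificially attenuated. The
MAP is the argmax of the smoothed `(P, C)` marginal (matching the
density-based presentation of the posterior); a best-raw-draw variant is
available. Credible regions are highest-density superlevel sets whose
enclosed mass is computed by quadrature on the KDE grid; a secondary local
maximum within 80 % of the global peak flags multimodality.

## Synthetic validation and what it shows

The validation harness generates `Y_k^S = Y_k^{M0} + ε_k` with
`ε_k ~ N(0, (f·|Y_k^{M0}|)²)` from a ground-truth grid node (or from held-out
simulations), clamps values to physical ranges, and runs the full inference
pipeline. Noise levels are `f = 0 / 5 / 10 / 20 %` for none/low/medium/high;
the exact experimental noise model is unknown, so the levels are configuration
and the high level is deliberately generous.

The default experiment is scaled down to desk compute. The study geometry,
schema, grid, noise levels, and truth points were fixed up front; the
per-node simulation protocol was revised once during development after
profiling the surrogate's sampling error (see below), not in response to any
accuracy threshold. The conditions: a 3-chromosome genome at one fifth of the
chr1/chr6/chr12 lengths (46/162/306 kb, rDNA interval on the third), nucleus
radius 350 nm (preserving genomic density), 30 rDNA beads at `V = 14 %`, a
3×3 `(P, C)` lattice `{40, 80, 160} × {35, 55, 85}` at fixed `(W, L) =
(30, 140)`, twelve replicas per node of 8×10⁴ steps each (4×10⁴
equilibration, 200 samples) — many short replicas because the replica count,
not the run length, sets how well a node estimate resolves the ~25 %
observable contrast between adjacent compaction nodes —
and a 166-observable schema mirroring the full 266-point compilation's
class mix at the sizes the small genome permits. Recovery truths sit at
`(P, C) = (40, 55)` and `(80, 85)` — each near an edge of the explored box.
The model-mismatch experiment regenerates truth data from simulations with
`V ∈ {5…30} %` while inferring against the unmodified `V = 14 %` grid.

A desk-scale caveat discovered during validation: two replicas of the same
node differ by roughly 20–40 % on slow distance observables, because each
fixed-duration run effectively averages only a couple of independent global
configurations (the slow arm modes relax far beyond the production window).
Recovery from node-mean synthetic data is unaffected (surrogate and data
share those values exactly), and the pooled `ρ_k` term keeps credible
regions calibrated. But experiments whose truth data come from *fresh or
held-out* simulations — the nucleolar-volume mismatch study and the
held-out-replica cross-check — see coherent, correlated observable shifts
that an independent-Gaussian likelihood reads as a parameter change;
quantitative error bounds for those experiments therefore require full-scale
sampling, and at desk scale they are exercised for their mechanics only.

What passing these tests does and does not show: the synthetic data inherit
the simulator's idealizations (homogeneous fiber, binary contacts, isotropic
imaging noise, independent Gaussian errors), so recovery accuracy measures the
*inference machinery* — identifiability, calibration of credible regions,
robustness to measurement noise — not the realism of the polymer model.
Real-data posteriors additionally absorb model error that this harness
cannot emulate.

One more scale effect worth recording: in the full nucleus, pericentromeric
chromatin is stretched relative to arm-internal regions because all 32
tethered arms crowd each other like a polymer brush around the SPB. On the
reduced 3-chromosome genome this sign reverses — with only six arms the
common-anchor geometry compresses centromere-spanning pairs instead — so
brush-stretching predictions are a full-genome property that the scaled
system deliberately does not test.

## Problem sizes

Desk-scale defaults were chosen so the full validation study (grid build plus
recovery runs) completes in minutes on one CPU: the scaled grid is 9 nodes ×
12 replicas ≈ 230–520 beads each; the subdiffusion check uses an ensemble of
twelve 200-bead phantom chains run for 2.4×10⁶ steps, and the static scaling
check a wide ensemble of 48 such chains run briefly (equilibrium statistics
need breadth, not duration, since chains start equilibrated). The full
16-chromosome,
144-node protocol is supported by the same code paths (configuration only)
but runs at cluster scale, and the packaged defaults do not attempt it.

## Known limitations

* The exact potential shapes and force magnitudes of the original simulation
  protocol are not public; the forms above are the simplest consistent
  choices, and equilibrium observables — not potential details — are the
  fidelity surface.
* Confined whole-nucleus runs at desk scale are not fully equilibrated in the
  slowest arm modes; the fixed-duration protocol keeps surrogate and truth
  data consistent, but absolute observable values at desk scale should not be
  read as converged equilibrium predictions.
* Hydrodynamics, replication, cell-cycle effects, and fiber heterogeneity are
  out of scope; the fiber is homogeneous outside the rDNA.
* The mode estimator's bandwidth affects mode-class observables at the few-nm
  level; experimental and simulated modes use the same estimator, which
  cancels to first order in the inference.
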