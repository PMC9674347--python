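# Methods

This note documents the models, conventions, and design decisions behind
`xlweaver`, in the spirit of the methods documentation of mature modeling
packages: what is computed, under which assumptions, with which defaults,
and what the synthetic benchmarks do and do not demonstrate.

## Coarse-grained representation

Each subunit's Cα trace is split into **rigid bodies** and **flexible
beads** from its per-residue confidence (pLDDT, read from the B-factor
column, the AlphaFold distribution convention):

* the confidence trace is smoothed by a centered moving average
  (`smoothing_window`, default 5 residues, odd; 1 disables smoothing) so a
  single low-confidence residue does not break a body — breaks should
  correspond to loop regions, not point dips;
* residues with smoothed confidence strictly above `plddt_threshold`
  (default 70) form candidate segments; segments shorter than
  `min_segment` (default 10) become flexible; `manual_breaks` force a
  boundary at a named residue regardless of confidence (used, e.g., to
  split a long α-solenoid into two bodies);
* inter-chain interfaces come from PAE matrices: a residue pair qualifies
  when its combined error (asymmetry resolved by `min`, the permissive
  published convention; `mean`/`max` are available) is strictly below
  `pae_threshold` (default 3.5 Å). Qualifying pairs are grouped into
  8-connected patches, patches below `min_patch` (10 pairs) are noise and
  discarded, and a patch can merge two segments into one rigid body using
  the pairwise prediction's relative orientation (largest patches first;
  incompatible placements of the same segment raise an error rather than
  silently averaging).

Two bead layers coexist. The **1-residue layer** (bead center = Cα) is
used for crosslink distances and chain connectivity. The **10-residue
layer** is used for excluded volume; its beads are chunked *within*
maximal runs of constant body assignment, so every excluded-volume bead is
purely rigid or purely flexible (a bead straddling a boundary would sit on
top of its own segment by construction). Bead radii use a single mean
residue volume, `r = (3 · n · 130 Å³ / 4π)^{1/3}`; the radii only feed a
soft-sphere penalty, so a per-residue-type volume table would add
parameters without changing behavior. Ten-residue bead centers are always
recomputed from the current 1-residue coordinates, which keeps rigid-body
internal geometry exactly pose-invariant.

## Restraint scores

All three terms are one-sided (upper-bound) harmonics — zero on a perfect
configuration, non-negative, continuous, and invariant under global rigid
motion:

* **crosslink**: per mappable link, `½ k_xl (d − 21 Å)²` for `d` beyond
  the 21 Å Cα–Cα restraint length of lysine-reactive MS-cleavable
  crosslinkers (boundary inclusive). Links that reference residues absent
  from the model are excluded from scoring and reported, never silently
  dropped.
* **excluded volume**: over 10-residue bead pairs not sharing a rigid
  body, `½ k_ev max(0, r_i + r_j − d)²`. Pairs on the same chain whose
  residue ranges are within `ev_min_seq_sep` (default 20) residues are
  excluded: at segment boundaries the covalent chain forces beads together
  and a soft-sphere term must not read that as a clash (the usual polymer
  convention).
* **connectivity**: consecutive 1-residue beads that do not share a rigid
  body are held within contact distance `conn_slack · (r_i + r_j)` by the
  same one-sided harmonic.

The total is a weighted sum. Weights have a Gaussian-likelihood reading:
`w = 1/σ²` with σ the credible violation scale of that restraint class at
sampling temperature 1. The assembly benchmark uses `σ = 5 Å` for
crosslinks — the dynamics margin of the 30 + 5 Å satisfaction convention —
and σ = 1 Å (weight 1) for excluded volume and connectivity, which keeps
packing firm while the crosslink term tolerates the slack it actually has.
The deterministic harmonic is a deliberate simplification of the Bayesian
crosslink restraints used by full-scale platforms: it is reproducible and
has no nuisance parameters, but it also has **no outlier tolerance** — a
consequence quantified below.

## Sampling

A campaign is `n_runs` independent Monte Carlo runs (default 20 × 10,000
frames = 200,000 configurations). Each run starts from a unique random
initialization: every rigid body gets a Haar-uniform rotation and a
centroid uniform in a cubic box; flexible beads are placed by a
contact-distance random walk from their nearest placed chain anchor. A
connectivity-only steepest descent (translation of bodies along their net
connectivity force, individual flexible-bead moves, backtracking line
search, so the trace is non-increasing) reconnects the chains before
sampling. Each MC step picks one mover uniformly among rigid bodies
(Gaussian translation σ = `trans_sigma`, rotation about the body centroid
with angle σ = `rot_sigma`) and flexible beads (Gaussian displacement),
and accepts by Metropolis at fixed temperature (an optional linear
annealing ramp is available but not used by default). One frame is
recorded per step, so frame counts are literal configuration counts.

Defaults: `trans_sigma` 8 Å, `rot_sigma` 0.2 rad, `bead_sigma` 3 Å —
tuned to give 30–50% acceptance on the bundled benchmark; `temperature`
1.0 in score units; box edge `max(1.1 × largest body diameter,
2.5 × (N · 130 Å³)^{1/3})`, i.e. just big enough for the parts, since
excess box volume only lengthens the distance bodies must travel to
assemble. Determinism: per-run seeds are children of the master
`SeedSequence` by run index, so the trajectory set is independent of
execution order.

## Ensemble analysis

Frames after an equilibration discard (first 20% of each run; 0 recovers
the literal all-frames behavior) are embedded in the 4-D score space
(crosslink, connectivity, excluded volume, total), standardized, and
clustered density-wise (DBSCAN on an even-stride subsample of ≤ 4,000
frames, `eps` 0.8, `min_samples` scaled to 2% of the subsample so thin
distribution fringes register as noise rather than spurious clusters;
remaining frames take the label of their nearest clustered neighbour).
The retained ensemble is the cluster with the best mean crosslink score,
ties broken by total score.

Retained frames (an even-stride subsample of `max_frames`, default 200,
keeps this tractable at any campaign size) are superposed onto a common
reference by residue-weighted least squares and grouped by single-linkage
pairwise bead RMSD at `rmsd_threshold` (20 Å). The largest structural
cluster yields:

* **centroid** — the member frame minimizing summed RMSD to the cluster
  (a medoid: always a physically sampled model);
* **precision** — residue-weighted root-mean-square of per-bead RMSF
  about the cluster-mean positions (Å);
* **localized densities** — per-subunit occupancy grids (Gaussian blur
  σ = 10 Å, voxel 5 Å, normalized to unit sum);
* **split-half correlation** — whole-complex densities of two halves
  (run-parity by default, random halves optionally) on a shared grid,
  Pearson-correlated over voxels supported by either half. Values near 1
  indicate independent runs converged on the same arrangement.

Crosslink satisfaction uses the inclusive 35 Å Cα–Cα convention (30 Å
crosslinker reach + 5 Å dynamics margin, both exposed as configuration).
The static form evaluates one model; the ensemble form takes the minimum
distance over models, so ensemble satisfaction is ≥ the static
satisfaction of any member. Zero mappable links yields an explicit
undefined result, not zero.

## Density maps and variants

`simulate_density` renders point masses with σ = resolution/(2√(2 ln 2))
(FWHM = nominal resolution, 23 Å by default — the scale of a subtomogram
average of a transport-train repeat). `rigid_fit` exploits the identity
that the overlap of the blurred model with a map equals the model masses
sampled from a once-blurred map, making the 6-parameter pose objective
cheap; derivative-free (Powell) local search from 24 starts (identity
orientation first, then Haar-random, all centred on the map's centre of
mass) recovers self-fits and planted transforms to well under 1 Å / 2° at
23 Å resolution. Envelope inclusion is volume-matched: the isosurface
threshold is chosen so the envelope encloses `1.21 × n_residues × 130 Å³`,
the standard convention when a deposition level is unknown.
`propagate_polymer` places copy *k* of a monomer at the *k*-th power of a
repeat transform.

Variant analysis is deliberately annotation-driven: domain ranges
(WD40/TPR/other) are user-supplied, variants are assigned by interval
lookup, and interface proximity is the minimum distance to any
other-subunit residue (proximal ≤ 10 Å), invariant under global rigid
motion and symmetric in query/partner.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
real protein geometry. Each rigid segment is a compact self-avoiding chain
(boustrophedon path over a jittered 3.8 Å lattice, randomly oriented, the
chain running along one axis so linkers leave through facing corners).
Segments of one subunit are stacked with a gap wide enough that the
interpolated linker clears both blobs' excluded volume; first segments of
all subunits are docked on a ring at the smallest radius where all residue
pairs clear a contact distance (`clearance`, 10 Å), so every subunit
touches two neighbours and the assembly closes. Confidence traces are
drawn at 85–95 inside segments and 40–60 in linkers, which straddles the
pLDDT-70 threshold such that smoothed segmentation recovers the generated
segments exactly; a layout is regenerated (deterministically, from spawned
seeds) until segmentation recovery, zero connectivity and excluded-volume
scores of the truth, and at least four crosslinkable contacts per ring
neighbour all hold.

Crosslinkable "lysines" are drawn at rate 1/5 among rigid-segment residues
— irregularly spaced, as in real sequences; a periodic lattice of sites
would hand the rod an artificial shift symmetry that makes link data less
informative than real crosslinks are. True links are sampled under a 30 Å
true-distance cap; decoys under a 50 Å floor, so a decoy can never satisfy
the 35 Å cutoff in truth. The intermolecular fraction defaults to 0.3 (the
census of a typical 98-link study); the recovery benchmark raises it to
0.6 and allocates intermolecular links round-robin over contacting
body pairs, because links internal to a single rigid body carry no
assembly information and a recovery experiment needs restraints on every
interface, as a curated modeling set would provide. PAE matrices are drawn
~N(2, 0.5) within bodies and across true interface blocks and ~N(20, 3)
elsewhere (declared constants, not inference targets). What the generator
does **not** emulate: real fold geometry, spectral noise and FDR structure
beyond a flat decoy rate, heterogeneous crosslinker reactivity, and
conformational heterogeneity of the ground truth.

## The recovery benchmark, and what it shows

`run_benchmark` is the desk-scale end-to-end experiment: 4 subunits,
~400 residues, 6 rigid bodies, 40 noise-free links, 8 runs × 5,000 frames
(small enough for a single CPU in well under a minute, large enough to
exercise every stage). Typical outcomes: ensemble satisfaction 1.0,
split-half density correlation ≥ 0.95, cluster precision 14–17 Å, and
centroid-to-truth bead RMSD 16–22 Å.

Two structural facts about these numbers deserve emphasis, because they
are properties of the restraint class, not implementation defects:

1. **Recovery error ≈ reported precision.** A flat-bottomed 21 Å
   restraint is consistent with an extended family of configurations; the
   sampled ensemble spreads over that family and the truth is, by
   construction, one member of it. For an ensemble calibrated to its own
   score, the expected squared distance between the ensemble mean and a
   typical member *equals* the ensemble variance — so centroid-to-truth
   RMSD concentrates at about one cluster precision rather than well
   below it. The medoid adds to this: in a configuration space of ~1,200
   dimensions no sampled frame lies near the ensemble mean, and the
   medoid-to-mean distance is itself a large fraction of the precision.
   Reported precision should therefore be read as the honest scale of the
   recovery error, not as a bound that the error sits comfortably inside.
2. **Quadratic restraints absorb decoys.** With a 20% decoy fraction the
   sampler *actively satisfies* the false links — a quadratic penalty has
   unbounded pull and no outlier plateau — so decoys do not reliably
   surface in the violated set of the recovered ensemble; and at
   ~15 Å cluster precision, the min-over-models satisfaction statistic is
   so permissive that even unrestrained residue pairs 50–70 Å apart in
   truth dip below 35 Å in some member. Detecting planted decoys by
   ensemble violation would require both an outlier-tolerant (e.g.
   Bayesian or capped) crosslink term and cluster precision of a few Å;
   neither holds for this deterministic pipeline at this data density.
   The decoy distances are computed and reported so this behavior is
   measured, not hidden.

Passing the benchmark therefore demonstrates: the sampler assembles the
complex from random placements, independent runs converge to the same
solution family, the data are fully satisfiable by the retained ensemble,
and the uncertainty report is of the same size as the actual error. It
does not demonstrate few-Å accuracy, decoy identification, or anything
about real (non-synthetic) data.

## Numerical conventions

* Residue numbering is 1-based; chain/protein names are case-sensitive.
* Ensemble coordinates serialize at 3 decimal places (PDB precision);
  round trips are exact at that precision. Confidence round-trips at the
  2 decimals of the B-factor column. The generator rounds its coordinates
  at creation, so emitted files are byte-stable under re-emission.
* Densities use truncated (3σ) Gaussian kernels; grids are centred on the
  data bounding box.
* Superposition is weighted Kabsch with proper rotations only
  (det = +1); mirror images are never silently aligned.
* Ties in interface merging go to the larger patch; ties in retained-
  cluster selection go to the lower total score.

## Known limitations

* The crosslink term is deterministic; ψ/σ-style nuisance weighting is an
  extension point, with the consequences for decoy robustness described
  above.
* Single fixed temperature; no replica exchange.
* One copy per protein (no ambiguity resolution over stoichiometries).
* The exact inclusion percentages of a deposited map depend on its
  isosurface threshold; the volume-matched default is a convention, and
  reproducing a published percentage requires matching that study's
  threshold choice.
* mmCIF is read but not written; ensembles are written as multi-model PDB
  plus a CSV score sidecar.
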