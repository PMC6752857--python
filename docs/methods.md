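# Methods

## Problem and model

Given multi-replica MD ensembles of the same receptor in two conditions
(ligand-bound and free), the package asks, per structural region and
descriptor, whether the two conditions' descriptor distributions differ,
by how much, and whether the difference exceeds what replica-to-replica
variability produces by chance. The analysis makes no dynamical model
assumptions beyond those implicit in the descriptors; its one essential
statistical commitment is that the **replica is the exchangeable sampling
unit**. Frames within a replica are strongly time-correlated and are never
treated as independent: they are pooled for point estimates, and whole
replicas are resampled for significance.

## Data model

A condition is a `TrajectoryEnsemble`: an ordered atom topology shared by
all replicas, plus per-replica `(frames, atoms, 3)` coordinate arrays in
Ångström. Topologies carry per-atom mass, van der Waals radius (Bondi),
chain, author residue numbering (insertion codes are part of residue
identity), a component label (receptor α/β chain, ligand MHC/peptide) from
the user's chain→component config, and hydrogen-bond annotations. On-disk
format is multi-model PDB, one file per replica, read and written through
MDAnalysis; when alternate locations are present the highest-occupancy
conformer is kept. Donor/acceptor/polar-hydrogen flags are assigned from
elements and first-frame covalent geometry (H within 1.25 Å of an N/O/S of
the same residue), so stripped-down structures without explicit
annotations still work.

Regions are named inclusive residue ranges on one chain (e.g. the six CDR
loops, AB loop, V/C linkers, helices and strands of a TCR). Their numbers
are configuration, not code: for real systems they must be supplied per
structure.

## Descriptors

- **DIST** (Å): distance between mass-weighted centroids of two regions,
  the convention of the standard trajectory tools.
- **RG** (Å): mass-weighted radius of gyration of a region's atoms.
- **SASA** (Å²): Shrake–Rupley with probe 1.4 Å and 960 sphere points per
  atom (both overridable), summed over the region's atoms; occlusion is
  computed over a configurable *context*. Passing the receptor components
  as context on the bound ensemble gives the "ligand removed" mode: the
  same frames scored as if the ligand were absent, isolating conformational
  change from simple burial. The rolling-probe evaluation is delegated to
  biotite with the topology's own radii.
- **RMSF** (Å): per replica, every frame is superposed onto that replica's
  first frame by mass-weighted least squares (Kabsch) over a fit region;
  the RMSF of a residue is the RMS deviation of its representative atom
  (Cα by default) from its time-average position, then averaged over
  replicas. The first frame is used as the fit reference to avoid
  iterative-mean ambiguity; since deviations are measured from the
  time-average position, not the reference, this choice only affects the
  fit, not the definition. For condition comparison RMSF enters as one
  value per replica (the region mean) — it is already a time aggregate, so
  a per-frame series would be fictitious.
- **Hydrogen bonds** (count): a donor–acceptor pair across two disjoint
  selections is bonded in a frame when the donor–acceptor distance is
  ≤ 3.5 Å and the hydrogen–donor–acceptor angle is ≤ 30° for some hydrogen
  covalently attached to the donor (defaults of the common MD tools;
  overridable). `hbond_frequency_table` pools occupancy fractions over all
  frames and replicas; pairs that never form are absent rather than
  zero-valued.

## Difference statistics

For a descriptor X with pooled values in both conditions:

- **d** = X̄_bound − X̄_unbound. Signed, in descriptor units.
- **d/r**: d normalised by r = extent of the union of the two conditions'
  [2.5th, 97.5th] percentile intervals (linear-interpolation percentiles,
  each condition trimmed on its own distribution before the union).
  Requires ≥ 40 pooled values, else the trimming percentiles are
  ill-defined and an `InsufficientDataError` is raised; an all-identical
  sample raises `DegenerateRangeError`.
- **tvd** = ½ Σ_bins |p₁ − p₂| over 100 equal-width shared bins spanning
  the pooled min–max, each histogram normalised to unit mass. Exactly 0
  for identical samples and exactly 1 for disjoint supports. The bin count
  is configurable; a note is attached to the result whenever halving the
  bin count moves tvd by more than 0.05, since histogram TVD on small
  samples is bin-sensitive. Fewer than two distinct pooled values returns
  0 with a warning.
- **Cohen's d**: mean difference over the pooled standard deviation, for
  users who want the conventional effect size.

## Significance by replica-level resampling

The 2n replicas of both conditions are merged; 1000 times (configurable)
two groups of the original condition sizes are drawn **with repetition**
from the merged pool and the statistic recomputed between them. Drawing
with repetition makes this a bootstrap-style null rather than a strict
permutation; it is implemented exactly as specified, and the observed
statistic is not added to the null set. q is the fraction of resampled
statistics **strictly smaller** than the observed one (ties count as not
smaller, so a degenerate all-zero null yields q = 0). Signed statistics
are resampled on their signed values and masked two-sided: a value
survives when q ≥ 0.95 or q ≤ 0.05. The sign-free tvd is masked one-sided
(q ≥ 0.95). Masking replaces non-significant values by zero in the summary
table; the unmasked table is always written alongside.

Degenerate resamples are defined to be zero difference (a group pair with
zero trimmed range or zero pooled variance contributes statistic 0), which
only arises for constant inputs.

## Replica-variance bootstrap

For group sizes n, two groups of n replicas are drawn with repetition
(10 000 times by default) and the absolute difference of the two group
means recorded (replicas weighted by frame counts). For iid replica means
the expected value follows a 1/√n law, so the percent reduction relative
to n = 1 is ≈ 68% at n = 10 and 80% at n = 25 — the basis for choosing a
replica budget, and the chance-level yardstick behind the 6% occupancy
filter of the H-bond difference map.

## H-bond network difference

The union of both conditions' occupancy tables yields per-pair records
with Δ = freq_bound − freq_unbound (missing pairs count 0). Records with
|Δ| above the threshold (default 0.06) are exported as cylinders whose
endpoints are the time-averaged donor/acceptor positions over the bound
ensemble (reference choice; configurable by passing another ensemble) and
whose radius is proportional to |Δ|; positive Δ renders red, negative
blue. Intra- and inter-chain bonds are both emitted, tagged by chain pair.

## Synthetic generators

`generate_descriptor_series` draws descriptor values from a hierarchical
model: replica means ~ Normal(grand_mean + Δ·[bound], between_replica_sd²),
frames AR(1) around the replica mean with stationary sd within_replica_sd
and lag-one coefficient φ. Defaults (10 replicas × 1000 frames, between
0.5, within 1.0, φ = 0.8) mirror a ten-replica, 100 ns-per-replica study
design with strongly autocorrelated frames. The AR(1) knob exists to test
that pooling frames for point estimates while resampling whole replicas
for significance stays calibrated under within-replica correlation — the
test suite verifies flag rates are unchanged between φ = 0 and φ = 0.9.

`generate_toy_ensemble` builds a geometric stand-in for a receptor–ligand
system: two 16-residue backbone-only chains (N, H, Cα, C, O per residue;
Bondi radii, standard masses) 10 Å apart, each with a central 5-residue
interface loop bulging 2.5 Å toward the partner, stems and tails as distal
controls, and optionally a rigid ligand slab 4 Å beneath the loops in the
bound condition. Frames are the reference plus rigid per-residue Gaussian
jitter (rigid so covalent geometry and H-bond annotations stay valid):
loops default to 1.0 Å free vs 0.5 Å bound (interface rigidification),
stems 0.3 Å; the bound chain-A loop is shifted 0.9 Å toward the partner (a
typical clearly-significant interface displacement); per-replica rigid
region offsets (0.15 Å) make replicas distinct but exchangeable. One
designated inter-chain hydrogen bond is switched per frame by a Bernoulli
draw (donor–acceptor 2.9 Å when formed, 5.0 Å when broken, ideal angle)
with per-condition probabilities (defaults 0.3 bound / 0.5 unbound, i.e.
fewer inter-chain bonds when bound). Everything is deterministic given the
seed.

What the toy does **not** emulate: side chains, realistic secondary
structure, solvent, force-field energetics, anharmonic or multi-state
kinetics, and time correlation within geometric trajectories (frames are
independent given the replica). Passing tests therefore demonstrate the
correctness and calibration of the measurement and inference machinery,
not that any real receptor behaves this way.

## Numerical choices and edge cases

- Coordinates in Å throughout; PDB round trips are exact to the format's
  0.001 Å precision.
- Percentiles use numpy's linear interpolation; histogram edges span the
  pooled min–max (a point mass gets a symmetric ±0.5 window so binning is
  defined); tvd is clipped to [0, 1] against float summation noise.
- Superposition uses scipy's weighted `align_vectors`; a fit region with
  fewer than 3 atoms or collinear geometry raises `FitError`.
- SASA of a region is the sum over its atoms' exposed areas; atoms outside
  the context never occlude.
- All stochastic operations accept explicit seeds or generators; pipeline
  runs log seeds and parameters and are bit-reproducible given the same
  config and seed.
- Test and example problem sizes (e.g. 10 replicas × 50–200 frames, 500
  calibration datasets, 8-replica toy ensembles) were chosen as the
  smallest sizes at which the checked quantities are statistically stable.

## Known limitations

- Histogram TVD is biased upward for small samples (few values per
  condition, e.g. per-replica RMSF summaries); the resampling null shares
  the bias, which keeps q roughly calibrated, but tvd point values on
  tiny samples should be read with care (bin-sensitivity notes flag this).
- No multiple-testing correction is applied across descriptors; with ~60
  rows, a handful of masked-in cells are expected under a global null.
- The resampling null draws with repetition, so duplicated replicas shrink
  null statistics slightly relative to a strict permutation; with ≥ 10
  replicas per condition the effect on the 5% tails is small (verified by
  the calibration tests).
- The canonical-loop-shape clustering sometimes reported alongside these
  descriptors is out of scope; Cohen's d is provided for any user-supplied
  per-replica shape descriptor.
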