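# ensdiff

Descriptor-level comparison of a receptor's conformational ensembles in two
conditions — bound to its ligand vs. free — from multi-replica molecular
dynamics trajectories.

The motivating setting is T-cell receptor (TCR) dynamics: does binding of a
peptide–MHC ligand change the dynamics of the TCR's CDR loops, AB loop,
variable/constant linkers and constant-domain elements in a conserved way?
The package is agnostic to the system: any two-chain receptor with named
regions and replica trajectories in multi-model PDB format works, and a
synthetic generator builds fully controlled toy systems so every stage can
be exercised without running MD.

## What it computes

**Descriptors** per region, replica and frame:

- `DIST` — distance between the mass-weighted centroids of two regions (Å)
- `RG` — mass-weighted radius of gyration, √(Σ mᵢ|rᵢ−r̄|²/Σ mᵢ) (Å)
- `SASA` — rolling-probe (Shrake–Rupley) solvent-accessible surface area
  (Å², probe 1.4 Å), with a "ligand removed" mode that scores the bound
  condition's frames as if the ligand were absent
- `RMSF` — per-residue root mean square fluctuation after least-squares
  superposition of every frame onto the replica's first frame (Å)
- `n of H-bonds` — geometric hydrogen-bond count between two selections
  (donor–acceptor ≤ 3.5 Å, H–donor–acceptor angle ≤ 30°)

**Statistics** per descriptor, bound minus unbound:

- d = X̄_bound − X̄_unbound (pooled means over all frames and replicas)
- d/r = d divided by the range of the union of the two distributions, each
  trimmed to its central 95% (2.5–97.5 percentiles)
- tvd = ½ Σ_bins |p_bound − p_unbound|, the total variation distance
  between the empirical distributions over shared histogram bins ∈ [0, 1]

**Significance** treats the replica as the sampling unit: the 2n replicas
are merged, two groups of n are redrawn with repetition 1000 times, the
statistic is recomputed between them, and q is the fraction of resampled
statistics strictly smaller than the observed one. Values outside the top
or bottom 5% of the resampling null are kept; everything else is masked to
zero in the summary table (the sign-free tvd uses the top tail only).

Also included: Cohen's d, a replica-variance bootstrap (how much the
between-group difference shrinks as group size grows), and hydrogen-bond
network difference maps exported as 3D cylinders (radius ∝ |Δoccupancy|,
red = more occupied when bound, blue = more occupied when free, default
filter |Δ| > 6%).

## Worked example

```python
from ensdiff import (EnsembleComparison, ToyEnsembleSpec,
                     generate_toy_ensemble)

spec = ToyEnsembleSpec(seed=5, n_replicas=6, n_frames=20)
bound, unbound, regions = generate_toy_ensemble(spec)
model = EnsembleComparison(bound, unbound, regions)
result = model.fit(n_perm=100, seed=3)
print(result.summary())
```

prints (abridged):

```
Ensemble comparison (bound − unbound); masked values are zero unless q ≥ 0.95 or q ≤ 0.05 (tvd: q ≥ 0.95 only)
                     d_over_r        d    tvd units_d
descriptor
DIST loopA-loopB       -0.290   -0.747  0.692       Å
RG loopA               -0.137   -0.213  0.000       Å
SASA loopA             -0.573 -146.974  1.000      Å²
SASA loopA noligand    -0.273  -39.630  0.658      Å²
RMSF loopA                NaN   -0.777  1.000       Å
RG stemA                0.000    0.000  0.000       Å
...
n of H-bonds            0.125    0.750  0.000   count
```

Reading the table: the toy's bound condition rigidifies and shifts the
interface loops and attaches a ligand, so the loop rows survive masking
with negative d — the loops are closer together (DIST −0.75 Å), buried by
the ligand (SASA −147 Å²) and less mobile (RMSF −0.78 Å) when bound —
while distal regions (`stem`, `tail`), which were generated identically in
both conditions, are mostly masked to zero. RMSF contributes one value per
replica, too few for the percentile-based d/r, hence NaN there.

The same flow runs from the shell on files:

```bash
ensdiff simulate --out toy --n-replicas 6 --n-frames 20 --seed 5
ensdiff report toy/system.yaml --out toy_results --n-perm 1000 --seed 3
```

which writes `summary_masked.tsv` / `summary_unmasked.tsv`, per-descriptor
histogram TSVs (`bin_left, bin_right, count_bound, count_unbound`), a tidy
per-frame descriptor table, the H-bond cylinder export
(`x1 y1 z1 x2 y2 z2 radius sign_color ...` plus a PyMOL CGO script) and a
JSON bundle with every statistic, q value and seed.

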