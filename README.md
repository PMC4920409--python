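# edgesync

Task-locked differential-synchronisation edge analysis for block-design
fMRI. Given a 4D BOLD run, a brain mask and a trial-onset table with two
conditions, `edgesync`:

1. removes baseline drifts (regression on a constant + linear + low-frequency
   discrete-cosine basis, default cutoff 1/90 Hz),
2. cuts the run into fixed-length trials and normalises each (voxel, trial)
   series to mean 0 / sd 1,
3. computes per-condition effect-size time courses `s_i(t) = mu_i(t) / sigma_i(t)`
   across trials, the pairwise synchronisation `theta` (Fisher z-transform of
   the positive Pearson correlation between effect-size courses), and the
   differential synchronisation `z = theta_A - theta_B` for every voxel pair,
4. applies a rank-preserving Gaussianisation to the `z` triangle (exact normal
   scores, average ranks for ties) and thresholds the top fraction of edges
   (1% -> z_t = 2.33); edges shorter than 15 mm are excluded,
5. scores every retained edge by its local edge density `D_e`: the fraction of
   suprathreshold pairs crossing between the closed 26-adjacency
   neighbourhoods of its endpoints (27 x 27 = 729 pairs for two full interior
   neighbourhoods; 18- and 6-adjacency are selectable),
6. builds a permutation null by Bernoulli(0.5) task-label swaps per trial
   (the same swap vector for all voxels), re-running the whole pipeline per
   replicate, and computes the empirical false-discovery rate
   `Fdr(d) = (1 - F0(d)) / (1 - Fz(d))` with the prior null probability fixed
   at 1; edges with `D_e` above the smallest density where `Fdr < alpha` are
   significant,
7. exports a per-voxel hubness map (significant-edge endpoint counts) as
   NIfTI, a TSV edge table, the Fdr curve and a JSON run manifest.

Two runs of the same task can be combined by a conjunction analysis
(element-wise minimum of the normalised `z` values) before thresholding.

## CLI

Generate a synthetic fixture with two planted 3x3x3 clusters responding in
condition A, then run the pipeline on it:

```sh
edgesync simulate --dims 10 10 10 --trials 20 --trial-length 16 \
    --cluster 0,3,3:3,3,3:A:2.0 --cluster 7,3,3:3,3,3:A:2.0 \
    --seed 1 --out-dir fixture/

edgesync -v run --bold fixture/run.nii --mask fixture/mask.nii \
    --onsets fixture/onsets.tsv --out-dir results/ \
    --permutations 100 --alpha 0.05 --seed 1 --highpass-hz 0

edgesync inspect results/
edgesync hubness --edges results/edges.tsv --mask fixture/mask.nii --out hub.nii
```

`run` accepts `--config config.yaml` (keys = `RunConfig` fields, flags
override), repeated `--bold`/`--onsets` pairs for two-run conjunctions,
`--top-fraction`, `--min-distance-mm`, `--adjacency {6,18,26}`, and
`--condition-a/--condition-b` to choose the contrast direction (swap them
for the reverse contrast). The onset TSV has columns
`condition`, `onset_volume` (0-based), `length_volumes`.

## File formats

- **Volumes**: NIfTI-1 (4D series, 3D mask); voxel size and TR are read from
  headers and can be overridden. Voxel ids are assigned in ascending
  (x, y, z) lexicographic order of 0-based lattice coordinates.
- **Pairwise triangles**: condensed upper-triangle vectors (pair `(i, j)`,
  `i < j`, at position `i(2n-i-1)/2 + j - i - 1`). `edgesync.triangle`
  offers a raw little-endian float64 container with a JSON sidecar
  (`n_values`, dtype, caller metadata) for persistence.
- **Edge table** (`edges.tsv`): voxel ids, lattice and mm coordinates of both
  endpoints, normalised `z`, `D_e`, and the Fdr at that density.
- **Manifest** (`manifest.json`): all parameters, the derived `z_t`, the
  `D_e` cutoff, edge counts and every permutation seed.
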