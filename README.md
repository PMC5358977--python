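# vocamap

Vocal repertoire mapping and statistics for mouse ultrasonic vocalizations
(USVs).

Mouse pups emit ultrasonic isolation calls whose acoustic structure — flat
tones, frequency sweeps, chevrons, and "step" syllables with abrupt
frequency discontinuities — varies between genotypes in ways that simple
summary statistics (duration, bandwidth, mean frequency) can miss.
`vocamap` implements a repertoire-level analysis for researchers comparing
vocal phenotypes between two groups of animals:

1. **Frequency contours** (per-syllable dominant-frequency trajectories,
   kHz vs time) are read from CSV/JSON, or extracted from WAV recordings by
   a multitaper harmonic-F-test front-end.
2. **Repertoire map** — contours are mean-frequency subtracted and compared
   all-to-all with dynamic time warping (DTW mean squared error, kHz²); the
   distance matrix is embedded in 2-D with t-SNE (perplexity = 2^H for
   transition entropy H, default H = 5), so acoustically similar calls
   occupy adjacent map regions.
3. **Significance map** — each group's map density ρ_g(x, y) (Gaussian
   smoothing, σ = 4 map units) is bootstrapped (resample calls with
   replacement, default 1000×); at each grid cell the bootstrap density
   values are modelled by a 1–3 component Gaussian mixture chosen by AIC,
   and P_HT(x, y) = P(ρ_HT > ρ_WT) is evaluated in closed form.  Cells with
   P_HT < α′ or P_HT > 1 − α′ are flagged, with the Šidák level
   α′ = 1 − (1 − α)^(1/2^H) using the entropy H of the pooled map density
   as the effective number of comparisons.
4. **Step statistics** — the pooled density is watershed-segmented, regions
   are classified step/non-step by the majority step status of their member
   contours (blind to genotype), and the per-group step counts are tested
   with a Yates-corrected 2×2 χ² test.
5. **Acoustic statistics** — per-syllable duration/bandwidth/mean frequency,
   averaged per individual and compared by one-way ANOVA (the individual,
   not the call, is the unit of analysis).

A synthetic-repertoire generator (template families with per-individual
effects, jitter, and controllable per-group step prevalence) makes the whole
pipeline testable and calibratable without recordings.  See
`docs/methods.md` for the models, parameters and numerical choices.

## Worked example

```python
import vocamap as vm
from vocamap import density_significance as ds, step_analysis as sa

# 1. synthetic two-genotype repertoire: 5 pups/group, 100 calls each
cfg = vm.RepertoireConfig(step_probability={"WT": 0.69, "HT": 0.48},
                          calls_per_individual=100, seed=11)
calls = vm.generate_repertoire(cfg)

# 2. repertoire map: DTW distances -> 2-D t-SNE embedding
dist = vm.all_pairs(calls)
rmap = vm.embed(dist, transition_entropy=5.0, seed=11)

# 3. per-genotype densities and the bootstrap significance map
grid = ds.GridSpec.from_points(rmap.coordinates, margin=12.0)
idx = calls.group_indices()
rho = {g: ds.density(rmap, idx[g], grid, sigma=4.0, group=g) for g in ("WT", "HT")}
H = ds.embedding_entropy(ds.pooled_density(rho["WT"], rho["HT"]))
q_wt = ds.bootstrap_cell_distributions(rmap, idx["WT"], grid, 4.0, n_boot=500, seed=1)
q_ht = ds.bootstrap_cell_distributions(rmap, idx["HT"], grid, 4.0, n_boot=500, seed=2)
sig = ds.significance_map(q_wt, q_ht, alpha=0.05, H=H)

# 4. genotype-blind step classification and the 2x2 test
regions = sa.segment_regions(ds.pooled_density(rho["WT"], rho["HT"]))
labels = sa.classify_regions(regions, rmap, calls, grid)
table = sa.step_table(labels, calls)
chi2, df, p = sa.chi_square_2x2(table)
```

Output (printed by `python` with the f-strings in the example script):

```
map entropy H = 11.17 bits -> alpha' = 2.22e-05
cells with HT excess: 45, WT excess: 0
step fractions: WT 68.8%, HT 50.2%
chi2 = 35.12, df = 1, p = 3.09e-09
```

Reading the numbers: the pooled map carries ~11 bits of entropy, so the
Šidák correction treats the map as ≈ 2300 effective comparisons and flags
only cells where one genotype's density exceeds the other's with per-cell
probability beyond 2.2 × 10⁻⁵ — here 45 cells where the HT repertoire is
relatively denser (HT pups make proportionally more simple calls).  The
map-based, genotype-blind step labels recover the generating step
prevalences (69 % vs 48 %) to within sampling error, and the 2×2 χ² test
rejects equal step proportions decisively.

## Command line

Each stage is a `vocamap` subcommand operating on files:

```bash
vocamap generate --seed 0 --out contours.csv
vocamap extract recording.wav --out contours.csv      # WAV front-end
vocamap distances contours.csv --out dist.npy
vocamap embed dist.npy --entropy 5 --tol 1e-4 --seed 0 --out map.csv
vocamap significance map.csv contours.csv --sigma 4 --grid 100 \
    --nboot 1000 --alpha 0.05 --seed 0 --out sig.npz
vocamap steps map.csv contours.csv --jump 10 --out steps.json
vocamap stats contours.csv --out measures.csv --anova report.json
vocamap run --seed 0 --out-dir study/                 # full pipeline + manifest
```

`vocamap run` writes every stage output plus `manifest.json` recording the
configuration and a SHA-256 hash of each artifact; rerunning the same
configuration reproduces the hashes.

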