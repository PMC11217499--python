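# memtopo

Identification and correction of membrane-topography-instigated
clustering artefacts in single-molecule localisation microscopy (SMLM).

## The problem

SMLM point patterns of plasma-membrane molecules almost always look
clustered. Part of that clustering can be an artefact of membrane
topography: the plasma membrane is folded, ruffled and invaginated, so
different pixels of a 2D projection contain different *amounts* of
membrane. A molecule distributed completely at random **in the
membrane** then appears enriched wherever there is more membrane —
and classical cluster statistics (pair correlation, PC-PALM,
nearest-neighbour analysis) report it as clustered.

`memtopo` implements an image-based remedy plus the statistics needed to
evaluate it:

* **Correction.** Render the protein and a randomly distributed membrane
  marker (e.g. the lipid probe DiI) to count images, Gaussian-smooth
  both, normalise to a common intensity mean and subtract the marker
  image. Topography-instigated "clusters" cancel; genuine clusters
  survive as a positive excess. The difference image has zero mean by
  construction, and genuine clustering shows as a *positive skew* of its
  intensity histogram, quantified by the type-3 sample skewness

      b1 = (m3 / m2^(3/2)) * ((n-1)/n)^(3/2)

  and tested across simulation replicates with a Welch two-sample
  t-test.

* **Classical statistics**, for comparison: the band-counted pair
  correlation function

      g(r) = Σ_i Σ_{j≠i} δ(r < d_ij ≤ r+dr) / (π((r+dr)² − r²) n λ),

  its PC-PALM decomposition
  g(r) = B·exp(−r²/4σ²) + A·exp(−r/ξ) + 1 (stochastic blinking term +
  protein-organisation term), and nearest-neighbour distance analysis
  (exact KD-tree or Euclidean-distance-map variants).

* **Synthetic data generators** for three study designs: partition-ratio
  cluster datasets (a fixed number of localizations split between
  designated non-touching cluster disks and the rest of the field at an
  in/out density ratio R, nested across ratios), membrane-topography
  maps (per-pixel membrane amount M = layers × slope factor) with
  area-weighted sampling, and dimer fields with partial detection.

## Worked example

```python
import memtopo as mt

# A membrane with a fold (3 membrane sheets over a stripe) and one
# genuine protein cluster patch (6x enrichment over a disk).
mmap = mt.build_membrane_map(512, 512, [
    mt.Fold(60, 140, 100, 400, extra_layers=2),
    mt.Enrichment(380, 256, 20, factor=6.0),
])
protein = mt.sample_topography(mmap, 300_000, enrichment_on=True,  seed=1)
marker  = mt.sample_topography(mmap, 300_000, enrichment_on=False, seed=2)

imgs = [mt.gaussian_smooth(mt.render_histogram(t, 1.0), sigma=8.0)
        for t in (protein, marker)]
p, m = mt.normalize_common_mean(*imgs)
diff = mt.subtract(p, m)

print(f"difference-image mean: {diff.mean():+.2e}")
print(f"skewness b1:           {mt.skewness_type3(mt.intensity_values(diff, 40)).b1:+.3f}")
```

prints

```
difference-image mean: -3.90e-16
skewness b1:           +10.544
```

The mean is zero by construction (both images share the mean), and the
strongly positive skewness flags the genuine enrichment patch: the fold,
although it holds three times the localization density, cancels in the
subtraction because the marker sees the same membrane excess. Rerunning
with `enrichment_on=False` for the protein (a purely membrane-following
molecule, the CD59-like case) gives `b1 = -0.26` — a small sampling
fluctuation around zero: all of its apparent clustering was topography.

The same pipeline is scriptable from the shell:

```sh
memtopo study --ratios 1,2,3,4,6,8 --reps 8 --seed 1 --out study/
memtopo correct --protein cd59.csv --membrane dii.csv --sigma 8 --guard 40
```

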