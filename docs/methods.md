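# Methods

## The artefact and the correction

A 2D SMLM dataset of a membrane molecule is a projection of a folded
surface. Let M(x, y) be the relative amount of membrane contained in the
imaging volume above pixel (x, y). A molecule distributed uniformly *in
the membrane* is sampled in the projection with probability ∝ M, so any
spatial structure in M (folds, ruffles, collapsed filopodia, coated
pits) reappears as apparent clustering of the molecule. `memtopo`
models, detects and removes this artefact.

The correction uses a second channel: a membrane probe assumed to
distribute randomly in the membrane, hence sampled with the same weight
M. Both channels are rendered to per-pixel count images, smoothed with
a Gaussian (σ in pixels), normalised to a common intensity mean (fixed
at 1, so downstream statistics are scale-free) and subtracted
(protein − marker). Structure common to both channels — the topography —
cancels; protein-specific structure survives. Because both parents share
the mean, the difference image has exactly zero mean; *genuine*
clustering manifests as a positively skewed intensity histogram, while a
topography-only protein gives a symmetric (Gaussian-looking) histogram
even though the individual images look clustered.

Skewness is quantified with the type-3 estimator
`b1 = g1·((n−1)/n)^{3/2}`, `g1 = m3/m2^{3/2}` (central moments with
divisor n), evaluated over the difference-image pixels inside a guard
frame (default 40 px) that removes smoothing edge effects. Differences
between conditions are tested with Welch's two-sided two-sample t-test
on per-replicate b1 values (the 95% CI comes from the
Welch–Satterthwaite degrees of freedom). No multiple-testing correction
is applied when reporting the smallest ratio with p < 0.05, matching the
single-comparison framing of the study design; a Holm-corrected column
is emitted alongside for transparency.

## Synthetic data generators

The generators define the study conditions; they are first-class,
tested code.

**Partition-ratio datasets.** 52 designated cluster disks of radius
32 px are placed uniformly at random in a 2048 × 2048 px field such that
they neither overlap nor touch (pairwise centre distance strictly
> 2r) nor cross the image edge, covering f ≈ 4% of the area
(analytically 3.99%). A fixed total of N localizations is split between
the disk union and its complement so that the *average density* ratio
in/out equals R:

    n_in = round(N·R·f / (R·f + 1 − f)),    n_out = N − n_in.

In-disk points pick a disk uniformly (equal radii ⇒ equal areas) and a
position by rejection in the bounding square; out-points by rejection
from the full rectangle. Both rejection streams use a fixed chunk size,
so the accepted sequence is a deterministic function of the seed alone:
datasets at different ratios built from one seed are *nested* (the
lower-ratio dataset is a prefix subset per pool), mirroring the
sequential-addition design in which localizations are individually
numbered. The total N is a free parameter of the study design (the
reference datasets do not print it); the default is 500,000 for a
2048² field, which gives smoothed images with a clearly resolvable
cluster contrast, and it is always logged in the run config.

**Topography maps.** M = L·S with L ≥ 1 an integer stacked-layer count
(rectangular "fold" features add layers, modelling ruffles and collapsed
filopodia) and S = sqrt(1 + |∇h|²) ≥ 1 the slope factor of a Gaussian
height field h ("bump" features, parametrised by their maximum slope so
that max S = sqrt(1 + s²) is exact). This is a minimal model that
reproduces "more membrane per pixel"; it does not attempt realistic
membrane mechanics. Genuine clusters are modelled as an optional
enrichment field E ≥ 1 (disk patches) that multiplies the *protein*
sampling weight only: marker weight M, protein weight M·E. Feature
footprints are kept as ground-truth masks.

**Dimer fields.** n pairs on a W × H pixel grid (default 4048 pairs,
600 × 600): black molecules at distinct random pixels, each red partner
uniform on the 8 adjacent pixels. For black molecules on the image edge
the partner is drawn uniformly from the *in-bounds* neighbours (the
analysis window is the central 512 × 512 px, so edge handling never
reaches the statistics). Red molecules of different pairs may coincide
with each other or with black pixels; only black pixels are distinct.
Partial detection retains a uniform random subset of round(d·n) red
molecules, 0 < d ≤ 1. Black→red nearest-neighbour distances are read
from a Euclidean distance transform of the red raster, matching
pixel-resident molecule analyses.

## Statistics

**Pair correlation.** Band-counted estimator over annuli (r, r+dr]
(half-open towards larger r; with continuous coordinates the band
boundary is a measure-zero event, and the fixed convention keeps the
KD-tree implementation bit-identical to the O(n²) oracle):

    g(r) = Σ_i Σ_{j≠i} δ(r < d_ij ≤ r+dr) / (π((r+dr)² − r²)·n·λ).

Only origins at least `guard` (default 100 px for simulated data) from
the ROI border are used; *all* points count as neighbours, and
λ = |targets| / ROI area uses the full ROI. Under CSR, g ≡ 1.

**PC-PALM.** The measured g(r) of blinking fluorophores contains a
repeat-appearance peak even without clustering. The decomposition fitted
here is

    g(r) = B·exp(−r²/(4σ²)) + A·exp(−r/ξ) + 1,

where the Gaussian term is the repeat-appearance (centroid) correlation
already convolved with the localization-precision PSF pair — in closed
form, with B = 1/(4πσ²ρ), ρ the true molecular density — and the
exponential term models protein organisation with correlation length ξ.
σ is *fixed* from the mean localization uncertainty rather than
co-fitted, which removes the near-degeneracy between the blink-peak
width and short ξ on short curves (a co-fit would be possible but is
not exposed). Free parameters (B, A, ξ) are bounded non-negative and
fitted by trust-region least squares; "clustering detected" means the
fitted A exceeds twice its standard error. On blinking-only CSR data
the fit attributes the short-range peak entirely to B (A ≈ 0) and
recovers ρ from B.

**Nearest neighbour.** Exact Euclidean NN per guarded origin via
KD-tree (self-distance excluded for auto-analysis), or the
distance-map variant above. Summaries report mean, median, quartiles
and 5th/95th percentiles with type-7 (linear interpolation) quantiles —
the common default; the choice is only visible for tiny samples.
Partial detection of dimer partners inflates the *mean* NN distance
monotonically while the *median* is constant over detection fractions
0.9–0.5 (once at least half the pairs keep both members, the median
stays on the ≤ √2 partner distance; at full detection the median sits
one discrete distance value lower, so the constancy claim applies to
the 90–50% range).

## Workflows and defaults

`run_simulation_study` builds, per replicate, one layout and three
datasets on it: ClusA (protein), ClusB (a marker partitioning at the
same ratios to the same areas — i.e. topography-matched) and Rand (flat
membrane CSR). Two subtraction modes are produced: ClusA − Rand, where
designated clusters survive and skewness grows with R, and
ClusA − ClusB, where the matched marker cancels them (inside/outside
designated-area contrast ≈ 0 and no skewness trend). Defaults mirror
the reference study: ratios {1, 2, 3, 4, 6, 8}, 8 replicates, σ = 20 px,
guard 40 px.

`run_correction` applies the pipeline to a real or synthetic two-channel
pair: optional ROI crop, render (default pixel size = 1 table unit),
smooth (default σ = 8 px for cell-style ROIs; σ = 24 px suits
coarse-feature simulations; conclusions are stable across σ ≈ 4–20 px),
optional background correction, normalise, subtract, then skewness, PCF
(prot–prot, prot–marker, marker–marker) and NN outputs. Background
correction defines background as the area without protein
localizations: the protein occupancy mask is morphologically closed
(disk radius = smoothing σ) so that empty pixels inside the cell are not
classed as background, the mean marker intensity over the background is
subtracted, and foreground pixels that become negative are dropped from
the mask.

Snapshot splitting divides an acquisition into consecutive 1000-frame
windows (25,000 frames → 25 snapshots); a final partial window is kept
and flagged rather than dropped, which is the conservative choice when
the acquisition length is not an exact multiple.

## Numerical conventions and degenerate inputs

* Continuous coordinates, origin top-left; pixel (i, j) covers the
  half-open square [j·p, (j+1)·p) × [i·p, (i+1)·p). All interval
  membership (extents, ROIs, bins) is half-open, which removes boundary
  double-counting; a localization exactly on a pixel boundary belongs to
  the upper pixel.
* Rendering is a per-pixel count histogram (no per-localization
  Gaussian splatting): a single smoothing σ is applied afterwards, and
  splatting would only act as extra smoothing.
* Smoothing appends a one-pixel zero frame before filtering (reflective
  boundary outside it) and removes it afterwards; the frame value is an
  artifact convention, and all published statistics additionally apply
  guard areas, so the boundary mode is immaterial.
* CSV round-trips are bit-identical: floats are written as shortest
  round-trip representations and parsed with a correctly-rounded parser.
* Degenerate inputs error loudly rather than guess: constant input to
  the skewness (m2 = 0), zero-mean images in the normalisation, empty
  target sets, guards that exclude all origins, infeasible disk
  packings (rejection capped at 10⁶ attempts).
* Seeds: every generator takes an explicit seed and records it; the
  workflows derive per-stage child seeds from one root seed via hashed
  seed sequences and log them.

## What the synthetic data do and do not show

The generators emulate the *geometry* of the artefact: area-weighted
sampling, designated-density clustering, partial detection. They do not
model blinking kinetics (on/off photophysics), localization-uncertainty
blur (except in the PC-PALM forward tests), drift, chromatic offset or
fixation artefacts. Passing tests therefore demonstrate that the
pipeline separates topography-instigated from genuine clustering *when
the marker faithfully reports membrane amount*; on real data the
conclusions additionally depend on the marker partitioning randomly and
on acquisition-level corrections performed upstream. The absolute
skewness values depend on the total localization count N (more
localizations → less shot noise → larger b1 for the same geometry), so
they are comparable within a study design but not across different N;
the monotone growth of b1 with partition ratio and the ≈ 0 value at
ratio 1 are the N-robust statements.

## Problem sizes used in the test suite

The acceptance-style tests run the simulation study at the reference
conditions (2048², 500k localizations, 6 ratios × 8 replicates) and the
remaining checks at the sizes named in their docstrings; the whole suite
is sized to complete in minutes on a single core.
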