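# Methods

## Mobility statistic

For tracked foci with 3D positions in µm, every unordered pair contributes
a distance series d(t) over the pair's common contiguous frame range and a
change series Δd(t_n) = d(t_{n+1}) − d(t_n). Mobility is |Δd|/Δt in
µm/min. Two representations coexist deliberately: the signed change series
is kept on `PairDistanceSeries` (for line plots of distance drift), while
`mobility` takes the absolute value, giving the non-negative, speed-like
quantity that box plots summarize. The statistic is invariant under any
per-frame rigid transform of the whole scene — this is its point: nuclear
translation and rotation cancel exactly (verified to 1e-9 µm in tests), so
what remains is chromatin motion relative to itself. A 20-sample series
(0, 5, …, 95 min) yields 19 change values per pair; "up to 95 min" is read
as inclusive endpoints, which is the only reading consistent with 20
frames and 19 intervals.

Group comparisons pool all pair-interval mobility values per group.
Pooling (rather than per-cell averaging first) is the default because the
generator produces one nucleus per group; the `GroupData` container
accepts either, so per-cell aggregation is a caller-side choice.

## Detection and linking

Detection is multi-scale Laplacian of Gaussian on each 3D frame, with
scales expressed in µm and converted to per-axis voxel sigmas, so
anisotropic sampling (coarser z) is handled uniformly. Sub-voxel centroids
come from an intensity-weighted mean over ±2σ around each blob. The
per-axis sigma is floored at 1 voxel: LoG at sub-voxel scales amplifies
sensor noise into thousands of spurious maxima (observed directly during
development), and a real focus is never narrower than the sampling grid.
Linking is greedy mutual-nearest-neighbour between consecutive frames with
a hard displacement gate; with ≤ ~20 foci per nucleus the global-assignment
alternative changes nothing in practice, and the simpler rule is easier to
reason about. Tracks shorter than 2 frames carry no interval information
and are dropped. Both limitations (no occlusion handling, no gap closing)
are intentional; the synthetic tests quantify their effect via ground-truth
recovery (≥90% of planted tracks, mean error < half a voxel).

## Nuclear metrics

The heterochromatin index is the coefficient of variation of intensity
inside the nuclear ROI on a maximum z-projection, ×100. SD uses the
sample convention (n−1); the definition does not fix the denominator and
n−1 matches common imaging-software defaults — it is a `ddof` argument, so
the population convention is one keyword away. The index is gain-invariant
but offset-sensitive; background subtraction is therefore exposed but OFF
by default, and no cross-channel normalization is applied anywhere (a
histone-signal normalization would cancel exactly the contrast the index
measures). Automatic ROIs (Otsu on the projection, largest component,
holes filled) stand in for manually drawn outlines in pipeline runs;
explicit masks always take precedence.

## Rank tests

Both Steel variants standardize the pairwise Wilcoxon rank-sum with
mid-ranks and the tie-corrected variance
V = n1·n2/(N(N−1)) · (Σr² − N(N+1)²/4). Steel–Dwass refers |T|√2 to the
studentized range with k groups and infinite df; the Steel many-to-one
procedure refers |T| to the maximum of an equicorrelated multivariate
normal with ρ_ij = √(n_i n_j/((n_i+n0)(n_j+n0))) (0.5 at equal n),
evaluated by scipy's deterministic MVN rectangle integration. For pairs
small enough to enumerate (C(N, n1) ≤ 20 000) an exact permutation
p-value of the pairwise statistic replaces the asymptotic reference; for
Steel–Dwass this exact branch carries no additional multiplicity
adjustment — a documented small-sample limitation, acceptable because the
asymptotic branch (which embeds the adjustment) takes over exactly where
family-wise calibration becomes meaningful, and null simulations show the
family-wise error within the binomial 95% CI of nominal at n=20/group.
The exact many-to-one branch is restricted to the single-treatment case,
where it coincides with the exact rank-sum test. All tests are two-sided.
Stars: *** p<0.001, ** p<0.01, * p<0.05, else N.S.

## Genomics arm

Coordinates are 0-based half-open throughout; windows [i·w, (i+1)·w) tile
each chromosome with the last window truncated. Reads are assigned to
windows by midpoint — single assignment keeps Σcounts = #reads exact —
while bedGraph coverage is apportioned by overlap length. RPKM divides by
the true (possibly truncated) window length. Island RPKM counts any
overlapping read, because fragments (~200 bp) are not short relative to
islands. The heavy/light split is at methylation level 0.8 (≥ heavy).
Window correlations re-bin the raw reads at each size; zero-count windows
are included by default (an `include_zero` flag exposes the exclusion
variant, since published pipelines differ). The t test on island RPKMs is
on the raw scale, not log, configurable by transforming inputs. Hilbert
rendering uses the standard d2xy orientation, order k = ⌈log₄ n⌉ per
chromosome; cells beyond the track are NaN + masked so "unassigned" can
never be confused with "zero signal".

## Synthetic data

Time-lapse: foci are placed uniformly in the nucleus with a 4σ minimum
separation (a packing limit rejects impossible requests), take Brownian
steps of per-axis variance 2DΔt with radial reflection at the boundary,
and the whole configuration is then rigidly transformed (rotation about
the nuclear centroid, then centre translation — order fixed so tests are
bit-reproducible). Rendering: isotropic Gaussians of width `focus_sigma`
on a uniform intra-nuclear background (15% of focus amplitude), Gaussian
sensor noise with SD = amplitude/SNR. Defaults: 20 frames × 5 min,
6 foci, σ = 0.4 µm, nucleus radius 5 µm, voxels 0.5×0.25×0.25 µm,
SNR 10. The acquisition geometry mirrors the live-imaging setting the
package targets; SNR and voxel sizes are unreported there and were chosen
once as typical confocal values. Diffusion presets 0.05/0.01/0.002
µm²/min for the embryo/ESC/MEF-like groups reproduce the qualitative
ordering of interest with mobility medians of order 0.1 µm/min.

MeDIP: one latent per-window methylation level in [0,1] per chromosome — a
logistic-squashed Gaussian random walk, so the landscape has long-range
structure and channel correlation genuinely grows with window size — with
non-overlapping islands overlaid (heavy ~ U(0.85,1), light ~ U(0.10,0.55)).
Channel counts are negative binomial with mean ∝ background + level and
variance µ + φµ² (φ = `channel_noise`; φ=0 renders deterministic rounded
means so that equal-mean channels are bit-identical). The input channel is
level-independent. Defaults: 2 × 1 Mb chromosomes, 1 kb base windows,
100 islands, 200 000 reads/channel, φ = 0.1, background 0.05.

What a green test does *not* establish: the generator has no GC or
mappability bias, no fragment-length distribution, no unplaced contigs and
no real CpG-island geometry, so absolute correlation values on synthetic
data (≈0.86–0.97 across 2–10 kbp at the defaults) are higher than real
MeDIP comparisons produce; only the qualitative behaviour (positive,
increasing with window size; heavy>light separation) transfers.

## Numerical choices

Distances in µm always (voxel indices scaled before any geometry).
Rigid-invariance tolerance 1e-9 µm (float64 roundoff headroom on µm-scale
coordinates). The blob threshold is relative to the volume's intensity
range. Degenerate inputs return flags, not infinities: a zero-mean ROI
yields NaN index with `index_defined=False`; an all-heavy island set
refuses the t test with a note; a constant image detects nothing rather
than erroring. Seeds propagate explicitly (`default_rng`); derived seeds
are small integer offsets of the user seed.
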