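# Methods

## Stain model

Transmitted-light intensity in channel C obeys Lambert–Beer,
`I_C = I0_C · 10^(−A·ε_C)`, so optical density `OD_C = −log10(I_C/I0_C)` is
linear in the stain amount `A`. Base-10 logarithms are used throughout
(the convention of the colour-deconvolution literature); any consistent base
cancels in the compose→deconvolve roundtrip. The incident intensity `I0`
defaults to 255 per channel and is user-overridable; white-point calibration
is deliberately left to the caller. OD at pixel value 0 is guarded with
ε = 1 intensity level (`OD(0) = log10(255) ≈ 2.407`), keeping the map finite
without a special-cased channel.

The stain colour system is a k×3 matrix of per-stain OD vectors, normalized
to unit rows. The shipped defaults are the published Ruifrok–Johnston H&E
and H-DAB vectors; **they are configurable defaults, not measured values for
any particular scanner or staining batch**, and any user matrix is accepted
(JSON via the CLI, arrays via the API). Two-stain systems are padded with
the unit cross product of the two rows so the 3×3 system inverts; the third
deconvolved channel is a residual, returned and flagged rather than
silently dropped. Matrices with condition number above 1e6 are rejected
with the condition number in the error message.

Quantization: composing to 8-bit RGB and deconvolving back recovers amounts
to within |Δ| ≤ 0.02 when per-stain amounts stay ≤ 0.7 (moderate staining
density). The bound degrades at higher optical densities because a one-level
step at dark pixels spans a large OD interval — at amounts near 1.0 the
worst-case error is ~0.05. The roundtrip tests therefore draw amounts
uniformly on [0, 0.7].

## Maximum-entropy nuclear extraction

Amount maps are min–max quantized to 8 bits per image (the scaling is
returned/logged), because the histogram machinery operates on discrete
intensity levels. The two-class "maximum entropy" cut is Kapur's criterion:
the t maximizing the sum of Shannon entropies of the two renormalized class
histograms, in log base 2 (the base cancels in the argmax). Cut points that
strand all mass on one side are ineligible — the `log w` term of the
criterion diverges to −∞ as a class empties — and ties (which occur exactly
on runs of empty bins) break to the smallest t.

"Four equal sub-histograms" means four equal-width intensity sub-ranges
([0,63], [64,127], [128,191], [192,255]), not equal-mass quartiles. A
massless sub-range takes its midpoint as the cut, flagged. The four cuts
plus the three sub-range boundaries partition [0,255] into eight intervals;
the layer index is the interval index, ascending with intensity (hence
monotone in intensity by construction).

The second stage histograms the **eight layer indices** (not the original
intensities restricted by layer — the contract fixes this reading) and
applies one more Kapur cut on [0,7]; nuclei are the layers above the cut,
since nuclei absorb more haematoxylin and so sit at high OD. Users feeding
raw transmitted intensity instead of OD/amounts must negate it first.

The mode filter re-assigns each pixel the most frequent value in its
(2r+1)×(2r+1) window, r = 3 by default; windows are clipped at borders (no
padding) and ties break to the smallest value — deterministic and
orientation-free. It is computed exactly via per-value summed-area tables.

**Known limitation.** When the nuclei intensity mode straddles a sub-range
boundary cut very unevenly (a small sliver in the top layer, the bulk one
layer below), the second-stage cut on the 8-bin layer histogram can land
directly below the top layer, keeping only the sliver; the mode filter then
erases it. On the planted-disk suite (disks at amount 1.2 on a 0.1 field,
noise σ 0.05) this happens for roughly 1 in 40 random noise realizations;
the other realizations give Jaccard ≈ 0.97. It is a property of the
two-stage layer-index design, not of the implementation.

## Texture model and training

The feature is the blue channel, unchanged in scale — in H&E and
haematoxylin-counterstained IHC, nuclear staining makes blue the most
discriminative single channel, and nuclear morphology marks cancerous
cells. Each class is summarized by the mean and **population** variance
(divide by n) of the feature over its training region; at training-region
sizes the 1/(n−1) distinction is irrelevant to the MRF energy. Variances
are floored at 1.0 intensity² so constant regions cannot produce infinite
energies. The default pipeline fixes four classes — tumour, stroma,
lymphoid/inflammatory-necrosis, background — because splitting non-tumour
into its two morphologically distinct subtypes improves tumour detection;
the engine itself accepts any k ≥ 2.

## MRF segmentation

Singleton energy is the exact negative log Gaussian density
(`log σ + (f−μ)²/2σ² + ½log 2π`; the constant cancels in comparisons but
keeps the energy interpretable). The pairwise potential is symmetric Potts,
−β for equal neighbour labels and +β otherwise; the alternative 0/+2β
convention shifts the energy by a constant and cannot change the argmin. β
multiplies the pairwise term only and defaults to 0.9, the working value
for tissue cores. The neighbourhood is 8-connected by default (richer
smoothing for texture; 4-connected available); cliques are unordered pairs
counted once in the total energy, while the local energy sums over all
neighbours of a site, so local differences equal global differences.

All relaxers start from the per-site singleton argmin (deterministic, a
strong start, and it makes the β = 0 limit exact: with the prior off no
proposal can improve any site, so every scheme returns the
maximum-likelihood labelling). Schedules and visit orders:

* **Metropolis** (default): per sweep, each site in a seeded random
  permutation receives a uniformly random different label; accept if
  ΔU ≤ 0, else with probability exp(−ΔU/T).
* **MMD**: same proposals, but a worse move is accepted iff
  exp(−ΔU/T) ≥ α with fixed α (default 0.3) instead of a per-move uniform.
* **Gibbs**: each site resampled from exp(−U_local/T) normalized over
  classes, same annealing schedule.
* **ICM**: deterministic raster-order argmin of the local energy; a tie
  with the current label keeps it (strict descent, no oscillation);
  energy is non-increasing and fixed points are 1-flip stable.

The annealing schedule is geometric: T0 = 4.0, T ← 0.98·T per sweep, stop
when the fraction of changed sites falls below 1e−4 or after 1000 sweeps
(non-convergence returns the best labelling seen, with a warning).
Stochastic relaxers return the lowest-energy labelling encountered, so the
final energy never exceeds the initial one. Sweeps are sequential
single-site updates (numba-compiled); all randomness comes from one seeded
generator, making runs bit-reproducible. Typical 512×512 runs converge in
200–400 sweeps, a few seconds.

After segmentation, stroma and lymphoid/necrosis merge into one non-tumour
class: internal order (tumour=0, stroma=1, lymphoid/necrosis=2,
background=3) → (tumour=0, non_tumour=1, background=2).

## Evaluation

Counts are per pixel over the non-excluded raster; the positive class is
tumour. Explicit exclusion masks model regions too ambiguous to annotate.
Ground-truth background is excluded by default — the task is cancerous-cell
segmentation, and whether background was scored at all in comparable
studies is ambiguous — with `include_background=True` scoring it as
non-tumour instead. The false-positive rate is FP/(FP+TN), the complement
of the TN rate, which is the definition consistent with the identity
fp_rate = 1 − tn_rate; the variant FP/(FP+TP) is available behind a flag
for comparability. Zero denominators yield NaN entries flagged by name,
never exceptions.

## Synthetic data

`make_layout` thresholds a Gaussian-smoothed white-noise field at the
quantiles of the cumulative class fractions, giving blobby regions whose
realized areas match the targets to raster granularity. Defaults: 256×256
(512×512 for the parameter-recovery checks), fractions
0.35/0.30/0.20/0.15, blob scale σ = 12 px. The blue feature is drawn i.i.d.
N(μ_c, σ_c²) with the easy suite at means 40/100/160/220 and σ 15
(adjacent-class Bayes error ≈ 2% per boundary) and the hard suite at σ 35
(likelihood-only accuracy ≈ 0.70, so the spatial prior must do real work).
Training masks are class cores eroded by 4 px, guaranteed pure; RGB is
either the replicated feature channel (`gaussian` mode, so
`blue_channel(rgb)` is exactly the feature) or a full Lambert–Beer
composition with per-class stain amounts (`stain` mode).

What the generator does *not* emulate: spatial correlation of texture
within a class, staining gradients and batch variation, chromatic noise,
out-of-focus regions, and the low-contrast red/pink appearance of real lung
H&E material. Passing the recovery checks therefore validates the
estimator and optimizer under the model's own assumptions; it does not
certify accuracy on real slides, where the Gaussian single-feature model is
only an approximation.

## Problem sizes and numerical choices

Recovery checks run at 512×512 (single images) and the oracle-equivalence
checks at 100 random instances each — sizes at which every result above is
stable across seeds. Energies are accumulated incrementally from local
differences (float64; sequential updates make local and global differences
identical). Degenerate inputs (constant images, empty histogram ranges,
single-pixel training regions) are handled by flagged fallbacks rather than
errors wherever a sensible default exists, and by explicit `ValueError`s
where it does not (empty training classes, zero stain rows, singular
matrices).
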