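# Methods

## Problem

Fluorescent live-cell imaging is used to monitor cell replication:
across experimental groups the blue stain level correlates (negatively)
with replication activity. Because the number of cells captured per
field varies with the sampling location, raw intensity sums or positive-
pixel counts are not comparable between images; a usable readout must
first segment the cells and then average the stain over the segmented
area. The same segmentation machinery, extended with a multistage
variant, detects nuclei in immunohistochemistry (IHC) tissue images.

## Colour model and stain separation

Under the Lambert–Beer law the transmitted intensity of channel
$\lambda$ is $I_1(\lambda) = I_0(\lambda)\,e^{-\alpha c(\lambda)}$, so
the optical density $D = \ln(I_0/I_1)$ is linear in stain amount. Each
stain is a unit 3-vector of per-channel ODs; stacking them gives the
stain matrix $A$, a pixel's OD row-vector is $D = C A$ for stain
concentrations $C$, and deconvolution inverts this as $C = D A^{-1}$
(Ruifrok–Johnston colour deconvolution).

Numerical conventions:

* OD is computed as $\ln(I_0/I_1) \ge 0$ (the literal $\ln(I_1/I_0)$ is
  negative for absorbing pixels); $I_0$ defaults to full scale per
  channel and is configurable.
* Integer images are floored at intensity 1 before the log; float
  compositions are floored at $10^{-12}$, so forward-composed images
  round-trip their concentrations to $<10^{-6}$ before quantisation.
* A two-stain system is completed to a $3\times3$ basis with the unit
  cross product of its rows before inversion; the synthetic third
  channel is discarded. The built-in matrices are the fluorescence
  blue/background pair and the Haematoxylin/Eosin/DAB triple (rows are
  re-normalised; the printed Eosin row is ~0.2% off unit length).
* Deconvolved channels are re-expressed as intensities
  $(2^c-1)\,e^{-C_i}$ so stained pixels are dark, matching the
  segmentation's foreground-is-low convention; raw concentrations are
  available behind `output="concentration"`.

## Maximum-entropy segmentation

The segmenter treats foreground and background as two information
sources and maximises, over the cut-off $j$, the Kapur criterion: the
sum of Shannon entropies of the class distributions
$\{p_i/P(A)\}_{i\le j}$ and $\{p_i/P(B)\}_{i>j}$. Splits leaving a
class empty score $-\infty$; exact ties resolve to the smallest $j$
for determinism; natural logarithms throughout (the argmax is
base-invariant). The binary mask codes foreground 0, background
$2^c-1$.

A `printed` criterion variant,
$-\ln P(A)-\ln P(B)-H_A P(A)-H_B P(B)$ with raw entropy sums, is kept
for comparison. It is not the default because its $-\ln P$ terms
diverge as either class empties, so its argmax sits at extreme
tiny-mass splits; on the synthetic fixtures it yields near-zero recall
while the Kapur form recovers the known masks.

Behavioural notes established on the synthetic fixtures:

* Kapur's criterion balances class information, so with a very small
  dark population against a large bright one the cut lands in the
  bright class's lower tail (~2σ in) rather than mid-gap; populations
  with bounded, disjoint supports are recovered exactly.
* Constant or single-bin images never raise: they return a flagged
  degenerate result with empty foreground so batch runs survive blank
  fields.

### Multistage (IHC) variant

For tissue images a two-pass scheme is used on the Haematoxylin
channel: (1) the 8-bit range is split into four equal-width quarters at
fixed boundaries 63/127/191 — equal-width, not equal-mass, because the
quarter boundaries precede any entropy computation; (2) a
maximum-entropy point is located inside each occupied quarter (empty
quarters collapse); (3) the ordered boundaries stratify the image into
up to eight layers; (4) the layer-label histogram is itself
entropy-thresholded; layers at or below the cut are nuclei (a polarity
flag inverts this). If all mass falls in one quarter the result
provably reduces to the single-stage threshold of that sub-range.

The final mask is cleaned with a mode (majority) filter: each pixel
takes the most frequent value in its $(2r+1)^2$ window, $r=3$ by
default. Windows are clipped at borders (no invented padding) and
exact ties go to foreground, which favours recovering weak,
low-contrast nuclei pixels; both choices are configurable. The filter
is applied to the binary mask, not the gray channel.

Second-stage behaviour depends on population proportions: when nuclei
occupy a small fraction of the field and a third (cytoplasm-like)
population sits between nuclei and background, the layer-histogram cut
can absorb the middle class into the foreground. With nuclei-dense
fields (≥ ~25% nuclear area, typical of tissue cores) the cut isolates
the nuclear layers (Dice ≈ 0.98 on the three-population fixture).

## Quantification score

The pixel-mean score is
$s = \frac{1}{|F|}\sum_{(m,n)\in F} \mu(m,n)$, where $F$ is the
foreground pixel set and $\mu$ the stain magnitude. Because stain
channels are intensity-like, $\mu = 2^c-1-I_B$ by default so that more
stain means a higher score; `measure="raw"` averages $I_B$ itself.
Averaging (rather than summing) makes $s$ invariant to the number of
cells in the field; a uniform magnitude shift of $\delta$ moves $s$ by
exactly $\delta$. The divisor is the *cardinality* of the foreground
set (the only well-defined reading of the mask-normalised form). A
per-cell variant averages within-cell means over 8-connected
components, weighting each cell equally; the two modes differ whenever
cell size and stain level covary. Empty-foreground images yield a
flagged, score-less record rather than 0, which would silently mimic
"no stain".

## Group statistics

Per-image scores grouped by condition are compared with a one-way
ANOVA (classical between/within decomposition, $F$ upper-tail p), then
pairwise post-hoc tests using the pooled within mean square: LSD
(unadjusted two-sided t) and Tukey HSD (studentized range with $k$
groups, Tukey–Kramer standard errors under imbalance). The studentized
range tail comes from `scipy.stats.studentized_range`, accurate well
within the ±5e-4 needed to match three-decimal published tables;
an independent statsmodels implementation cross-checks the Tukey
p-values in the tests. Display formatting mirrors the usual
three-decimal convention with "< 0.001" below that floor. Zero
within-group variance flags the table as degenerate instead of
dividing by zero.

## Synthetic data generator

The generator provides the study conditions for every end-to-end test:

* **Fluorescence fields** (default 256×256): a flat gray background
  (transparent regions render gray under a digital fluorescence
  microscope; default 180) with non-overlapping elliptical cells
  (radius 8–16 px, mild eccentricity jitter, rejection-sampled
  placement). Each cell's stain magnitude $m$ is drawn from
  $\mathcal N(\text{stain\_mean}, 8)$ and applied by attenuating the
  background along the *blue-stain OD vector* with concentration
  $-\ln(1-m/255)$ — so the deconvolution step is exercised, not
  bypassed. Additive Gaussian pixel noise (σ = 3) is clipped and
  quantised to 8 bits. Cohorts use stain means 30/60/90 for
  low/mid/high replication groups. The recorded `true_score` is the
  exact pixel-mean score of the noiseless, unquantised blue channel
  over the true mask.
* **IHC composites** (default 256×256): 40 non-overlapping nuclei
  (radius 6–12 px) with Haematoxylin concentration U(0.7, 1.2) and DAB
  U(0, 0.3) over a uniform Eosin counterstain background (0.15),
  composed per pixel as $255\,e^{-CM}$ and quantised with σ = 2 noise.

All outputs are bit-reproducible from (spec, seed). What the generator
does **not** emulate: uneven illumination, chromatic aberration,
overlapping or touching cells, textured chromatin, out-of-focus blur,
and real stain-vector variation between batches. Passing tests
therefore demonstrate correctness of the algorithms under their own
forward model and clean separability conditions, not field performance
on real slides. Image sizes are kept at 256×256 (vs ~2560×1920 real
captures) because every stage is per-pixel or histogram-based and
scale-free; this is a package choice for fast, deterministic test
fixtures.

## Known limitations

* Fixed stain matrices only; no per-image stain-vector estimation.
* Region segmentation, not instance segmentation: touching nuclei are
  not split.
* Kapur thresholding assumes a meaningfully bimodal (or, multistage,
  multi-modal) histogram; very sparse foreground biases the cut into
  the background tail, and a dominant intermediate class can be
  absorbed into the foreground.
* Scores are not normalised across acquisition sessions; no
  illumination correction.
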