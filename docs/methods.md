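# Methods

## The model

`hmcnet` implements an attention-augmented residual network for 3-class
mammogram classification (normal / benign / malignant). The backbone is a
standard 50-layer bottleneck residual network trained from scratch with stage
widths 64, 256, 512, 1024, 2048 and input 224×224×3. Four γ-gated attention
blocks refine the stage graph:

* **HA1, HA2 (hierarchical self-attention)** after stages 1 and 2: queries,
  keys and values all come from the same stage output, so the block learns
  within-stage spatial dependencies (x1′ = HA1(x1, x1), x2′ = HA2(x2, x2)).
* **CA23, CA34 (multi-scale cross-attention)** between stages 2–3 and 3–4:
  queries come from the deeper stage; keys/values from the shallower stage
  after a 1×1 channel-matching convolution and bilinear resampling to the
  deeper stage's geometry (x3′ = CA23(x3, x2′′), x4′ = CA34(x4, x3′′)).

Each block computes, for query source X and key/value source Y of shape
(B, C, H, W) with N = H·W positions and d_k = C/8:

    Q = W_q X,  K = W_k Y,  V = W_v Y           (1×1 convolutions)
    E = Q′ᵀ K′                                   (B, N, N)
    A = softmax(E / √d_k)  over key positions
    Out = γ · reshape(V′ Aᵀ) + X

γ is a learnable scalar initialized to exactly 0, so every variant's initial
forward pass equals the plain backbone ("identity at initialization") and
attention strength is learned. The head is global average pooling over x4′
followed by a fully connected layer to 3 logits; probabilities are softmax.

Ablation variants share backbone parameter names: `baseline` (no attention),
`hierarchical_only` (HA1+HA2), `multiscale_only` (CA23+CA34), `hmc` (all
four). Parameter name-sets are nested accordingly, which the tests assert.

### Numerical and design choices

* **√d_k scaling.** The energy scaling is applied uniformly in all four
  attention blocks (it stabilizes the softmax; omitting it changes nothing
  structurally but worsens conditioning at large C).
* **Projection biases.** All 1×1 projections carry a bias initialized to 0;
  harmless at γ = 0 and consistent with common practice.
* **Softmax axis.** Over key positions (last index of E): each query position
  holds a distribution over key positions; rows of A sum to 1.
* **Resampling.** Bilinear with corner alignment off (half-pixel centers);
  constants are preserved exactly. The same routine serves the cross-scale
  adapter, preprocessing and heatmap resizing.
* **Memory guard.** The energy matrix is N² per batch item. Blocks refuse
  N > 4096 positions (a cap that still admits the 56×56 first-stage map of
  the default configuration) with a clear error; the cap is configurable —
  nothing is silently approximated.
* **Loss.** Standard cross-entropy L = −Σ_c t_c log p_c minimized with Adam
  (η = 1e-4 default, β = (0.9, 0.999), ε = 1e-8, batch 32). The epoch count
  is configurable (default 50).
* **Class imbalance.** No class weighting is applied.
* **Validation split.** 10% of training patients, held out patient-wise,
  evaluated un-augmented each epoch.
* **Autodiff engine.** All network computation runs on a compact reverse-mode
  automatic-differentiation core over numpy (`hmcnet.autodiff`): im2col
  convolution, batch normalization, max pooling, bilinear resampling, batched
  matrix products, softmax and cross-entropy, each with hand-derived
  backward passes validated against central finite differences in the test
  suite. Computation is float32 and deterministic for fixed seeds.

### Reduced presets

The `tiny` preset (input 64×64, all widths ÷8, full depth) brings one
training run to minutes on a CPU; the `micro` preset (one block per stage,
widths 8–32, input 32) exists for smoke tests. The acceptance-level training
check uses `tiny` on 300 phantoms (240 train / 60 held out, 140 epochs,
η = 1e-3) — problem sizes chosen so the full suite runs at desk scale.

## Explainability

Three CAM explainers target the post-attention stage-4 output x4′ (2048
channels at 7×7 by default), so attention refinement is visible in heatmaps:

* **Grad-CAM**: α_k = spatial mean of ∂y_c/∂A_k; CAM = ReLU(Σ_k α_k A_k).
* **Grad-CAM++**: pixel weights by the closed form in powers of first
  derivatives, α_ij = G²/(2G² + (Σ A)·G³), with zero-denominator pixels set
  to 0; channel weight Σ_ij α_ij·ReLU(G_ij) by default. A `literal_eq24`
  flag drops the ReLU(G) factor (the simplified aggregation some
  formulations print); which form produced any given published figure is
  generally not identifiable, so both are exposed.
* **Score-CAM** (gradient-free): each channel's min–max-normalized map,
  upsampled to input size, masks the input; the masked image's softmax
  confidence for the class weights the channel. Channel passes run in
  configurable chunks; results are chunk-size independent.

y_c is the pre-softmax logit for the gradient methods and the softmax
probability for Score-CAM; both are configurable. Heatmaps are bilinearly
resized to input resolution and min–max normalized into [0, 1]; a constant
pre-normalization map (where normalization is undefined) yields all zeros.

**Localization scoring**: heatmaps are binarized at `values ≥ threshold`
(default 0.5), the ground-truth mask is nearest-neighbor resampled to
heatmap resolution, and IoU = |∩|/|∪| is reported per sample with the
arithmetic mean over a set. An empty union scores 0. Published IoU levels
from a fully trained model on real mammograms are methodology context, not
test targets, since they require full-scale training on the real dataset.

## Data pipeline

* **MIAS format.** One whitespace-delimited annotation line per finding
  (id, tissue, class, severity, x, y, radius; NORM lines carry no ROI).
  Multi-finding images collapse to one record with label precedence
  malignant > benign and the union of ROI discs as the mask. MIAS
  y-coordinates are bottom-left-origin, so rows are flipped during mask
  construction (row = size − 1 − y). MIAS ships no patient ids; consecutive
  left/right film pairing (2 images per patient) reproduces the 161-patient
  structure of the 322-film set and enables patient-level splits.
* **Preprocessing.** Bilinear resize to the model input size, replication of
  the grayscale plane onto 3 channels, then (x − 0.5)/0.5 into [−1, 1].
* **Augmentation** (training folds only, fresh per epoch): brightness and
  contrast factors uniform in [0.8, 1.2], horizontal flip with probability
  0.5, rotation uniform in ±15° with zero fill — applied in the fixed order
  jitter → flip → rotate for reproducibility; the order is otherwise
  arbitrary. An offline expansion helper derives an exact target count of
  augmented images for fixed-budget regimes; the budget is a free
  configuration value.
* **Patient-level k-fold.** Patients are shuffled by seed and dealt into k
  groups whose sizes differ by at most one; every image of a patient lands
  in exactly one test fold, and disjointness is asserted programmatically
  after each split.

## Synthetic phantoms

The generator emulates the three classes at desk scale on a smooth
low-frequency background (Gaussian-filtered noise, mean ≈ 0.30):

* **normal** — background only, empty mask;
* **benign** — one bright blob with a smooth, near-circular outline (slow
  low-order boundary undulations only);
* **malignant** — an irregular core (stronger boundary modes) with 8–14
  radiating spicules extending 1–2 core radii, wide enough to stay
  resolvable after rasterization at the default sizes.

Lesion brightness follows the actual lesion support with a softened rim, so
the boundary shape — the class cue — is visible in the image, not only in
the mask; amplitude ranges overlap between classes so intensity alone does
not separate benign from malignant. The mask is the exact lesion support.
Samples are bit-reproducible from (label, size, seed), with per-sample seeds
spawned from the set seed so a sample's content does not depend on n.

What the phantoms do **not** emulate: breast boundary and pectoral muscle,
film artifacts and scanner noise, parenchymal texture classes, calcification
clusters, bilateral asymmetry, and realistic lesion co-occurrence. Passing
phantom-based tests therefore demonstrates that the pipeline, optimization
and explanation machinery work end-to-end and that the architecture can
learn shape-versus-texture distinctions — not clinical-grade performance on
real mammograms.

## Statistics harness

Metrics are computed one-vs-rest per class from the confusion matrix and
macro (unweighted) averaged — consistent with published per-fold F1 values
that are not the harmonic mean of the corresponding pooled precision/recall.
Overall accuracy is trace/total. AUC is macro one-vs-rest on softmax
probabilities (rank statistic); absent classes are skipped with a logged
flag. Fold aggregates are arithmetic mean ± sample standard deviation
(ddof = 1), reported at two decimals.

Model comparison over folds uses the Friedman test (average ranks on ties;
χ² approximation with k−1 df; an exhaustive-permutation p is available for
small k!^N) and the Nemenyi post-hoc test via the studentized-range
distribution with infinite df. The critical difference is
CD = q_α·√(k(k+1)/(6N)). The published comparison used q_α = 2.949, which
is shipped as the documented default for reproducing it; the standard
two-tailed Nemenyi value for k = 4 at α = 0.05 (≈ 2.569) is exposed as
`Q_ALPHA_NEMENYI_K4`. In the CD diagram, a rank gap reaching CD (boundary
included) is significant; smaller gaps join models into connectivity groups.

## Known limitations

* The full-size configuration trains only at impractical CPU cost; the
  package's training evidence comes from the reduced presets on phantoms.
* Attention is exact (dense N² energies) — no linear-time approximation —
  so very large feature maps are refused rather than approximated.
* Grad-CAM++ uses the closed-form first-derivative substitution, which is
  exact for ReLU-family score functions but an approximation wherever the
  score is not piecewise linear in the feature maps (e.g. softmax scores).
* The MIAS patient pairing is a convention (the dataset publishes no patient
  ids); any error in that assumption shifts the leakage-control unit from
  patients to films.
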