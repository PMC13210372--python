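# Methods

## Problem and pipeline

`neopain` assesses procedural pain in NICU infants from one synchronized
10-second multimodal clip: mono cry audio at 16 kHz, physiological series
at 100 Hz (heart rate, SpO2, respiratory rate, optionally mean arterial
pressure) with a 2-minute preceding baseline window, four facial action
channels at 30 fps, and context metadata (gestational age 24–44 w,
postnatal age 0–35 d, weight, ventilation flag). The output is a 4-level
ordinal pain assessment (0 none / 1 mild / 2 moderate / 3 severe) or an
explicit abstention that routes the case to a clinician.

The pipeline runs in six stages:

1. **Preprocessing** (`episodes_io`): wavelet denoising of physiology
   (Symlet-4, level-5 decomposition, soft universal threshold from the
   MAD of the finest detail band), resampling to an exact k/100-s grid,
   linear interpolation of gaps under 2 s and explicit NaN-marking of
   longer gaps; log-power mel spectrograms (128 bands, 2048-point FFT,
   hop 1024, Hann window, no center padding, floor 1e-10); segmentation
   into 10-s clips with 50% overlap, trailing residue dropped.
2. **Concept bottleneck** (`concepts`): 12 interpretable clinical
   concepts grounded in NIPS/PIPP-R/COMFORT-B items — facial C1–C4,
   vocal C5–C8, physiological C9–C12 — each with a binary clinical rule
   in native units and a graded activation in [0, 1] (logistic of the
   margin to threshold, scale 10% of the threshold, so the binary rule is
   exactly `activation > 0.5` for single-threshold concepts). Facial
   thresholds are stratified by gestational age (0.60 / 0.65 / 0.70 /
   0.75 across <28, 28–32, 32–37, ≥37 w); the F0-elevation cut is 450 Hz
   preterm, 500 Hz at term (≥37 w). All comparisons are strict. A
   parallel learned bottleneck (per-modality linear heads on 128-dim
   encoder embeddings, sigmoid, 3x12 matrix) is provided for concept
   supervision; the canonical vector takes each concept from its source
   modality row.
3. **Graph fusion** (`fusion_net`): concepts become 12 graph nodes with
   features `h_i = c_i * e_i + b_i` (learned 128-dim embedding and bias
   per concept; unavailable concepts are zeroed first and are therefore
   feature-neutral). A 2-layer MLP (hidden 64) scores ordered pairs on
   `[h_i; h_j; |h_i − h_j|]`; a row-wise softmax over j ≠ i yields a
   row-stochastic adjacency. Missing modalities zero all edges incident
   to their nodes, with surviving rows renormalized. Two GraphSAGE-style
   layers (`ReLU(W_self h + W_nbr Σ (Ã⊙M) h)`, hidden 128, mean
   aggregation) propagate over the gate-masked adjacency (per-edge
   sigmoid gates, deterministic at inference); mean-pooling over
   unmasked nodes gives the fused 128-dim representation.
4. **Evidential output**: `α = ReLU(W h_GNN + b) + 1` are Dirichlet
   parameters over the 4 levels; uncertainty `u = 4/Σα`, probabilities
   `p = α/Σα`; the system abstains when `u > τ` (default τ = 0.5).
   Probability ties break toward the higher severity and are flagged.
5. **Symbolic explanation** (`symbolic`): 18 rules in four categories
   (6 high-confidence, 5 moderate, 4 ambiguous, 3 no-pain) resolved in
   three tiers — Tier 1 physiological override (highest-weight firing
   high-confidence rule wins outright), Tier 2 weighted consensus vote
   (ties to higher severity), Tier 3 uncertainty escalation (u is raised
   by 0.1; abstain if the elevated u exceeds 0.5, else report the
   no-pain baseline). Guards compare activations to GA-resolved
   thresholds; any guard touching an unavailable concept blocks its
   rule. Ventilated infants get a dedicated protocol: C5–C8 suppressed,
   C9–C12 activations scaled 1.5x and clamped, a 6-rule subset replaces
   the standard set, and u is elevated.
6. **Personalization** (`learning`): per-infant adaptation touches only
   the additive adjacency-score offset ΔA and the evidential head;
   concept heads, encoders and graph weights are bit-identical before
   and after, preserving concept semantics.

## Training objectives

The multi-task loss is `α·L_concept + β·L_ordinal + γ·L_evidential +
δ·L_sparsity + ε·L_meta + ζ·L_contrast` with default weights
(1.0, 2.0, 0.5, 0.1, 0.8, 0.3). `L_concept` is mean BCE of the 3x12
heads on labeled clips. `L_ordinal` is the squared difference of
predicted vs true cumulative class distributions — an earth-mover-style
surrogate chosen because the scale is ordinal and no closed form is
canonical; distant misgradings cost more than adjacent ones.
`L_evidential` is the Dirichlet mean-square form (per-class Brier plus
variance term) with a KL-to-uniform regularizer on off-target evidence
whose coefficient anneals linearly from 0 to 0.1 over the first 10
epochs. `L_sparsity` is the mean L1 of the off-diagonal gated masked
adjacency. `L_contrast` is NT-Xent over paired augmented views
(temperature 0.1 by default). Supervised desk-scale training uses Adam
at learning rate 3e-3 for 30 epochs, batch 32 (a deliberately short desk-scale
schedule; at these cohort sizes it converges). The evidential head bias is initialized at
1 so that evidence units start active — with a zero-bias ReLU head all
logits can start negative, freezing p at uniform with zero gradient.

Meta-learning is first-order: the inner loop takes proximally
regularized SGD steps on the personalization parameters (5 steps,
learning rate 0.2, proximal weight 0.05 pulling toward the shared
initialization — a sample-size-adaptive trust region in the spirit of
implicit-MAML); the outer loop applies the adapted-parameter query
gradient to the shared initialization (outer rate 0.005). Episodes are
4-way (the four pain levels). Task construction refuses any
support/query clip overlap and any evaluation-infant occurrence, by id.

## Synthetic study conditions

The generator (`synthetic_data`) emulates NICU episodes with known
ground truth. Defaults (the study conditions): GA strata 15/35/30/20%
across <28/28–32/32–37/≥37 w; pain levels 25/30/25/20%; modality mix 75%
complete / 15% missing audio / 10% missing physiology; 5% ventilated
(ventilated episodes emit no audio); MAP monitored for 70% of infants;
per-infant expressivity ρ ~ N(0, 0.5²); measurement-noise scale 1.

Signal construction: HR baseline ~N(140, 10) bpm with a clip step of
+7% per pain level; SpO2 dips 1.6 points per level from 97% (Gaussian
transient); respiratory-rate CV 0.08 + 0.07 per level (smooth modulation
with ~0.5-s correlation); MAP +4 mmHg per level. Cries are 6-partial
harmonic stacks at F0 = 380 + 45·level Hz (+10 Hz at term) with per-cry
RMS 0.1 + 0.1·level, harmonic power fraction 0.85/0.60/0.25 at levels
1/2/3 (so the harmonic-to-noise ratio crosses the 0.5 rule only at level
3), and inter-cry pauses of 120 + 60·level ms; level 0 is silence.
Facial channels sit at logistic(1.4·level − 2.0 + GA attenuation + ρ)
with attenuation −0.5/−0.3/−0.15/0 across the GA strata. ρ additionally
loads on every modality (15 Hz, 0.02 RMS, 2% HR, 0.3 SpO2 points, 0.01
RR CV, 0.5 mmHg per unit) so that expressivity is a genuine cross-modal
per-infant trait. All constants were chosen once so that clean signals
decisively clear or miss the clinical thresholds.

Ground-truth concept labels are defined as the clinical rules applied to
the clean (pre-measurement-noise) signals; at noise scale 0 the
detectors reproduce them exactly, by construction. Measurement noise is
AR(1) for HR/SpO2/MAP, white for RR and audio, smoothed white for facial
channels.

What the generator does **not** model: real cry acoustics (formants,
glottal dynamics), facial appearance (channels stand in for a video
pipeline), drug effects, movement artifact, sensor detachment patterns,
or correlated multi-system physiology. Passing tests therefore show that
the pipeline recovers the structure this generator encodes — threshold
rules, ordinal separability, per-infant shifts, site heterogeneity — not
clinical performance on real infants.

## Reference experiment protocols

Fixed in `neopain.experiments` (sizes chosen to run on one CPU in
minutes):

* **Main cohort**: 200 infants x 4 episodes, default conditions, 80/20
  infant-disjoint split. Reports rule-based concept recovery (macro-F1
  of firing vs clean-signal truth) and held-out accuracy of the trained
  fusion model on detector activations.
* **Uncertainty ensemble**: 130 complete-modality infants; mean
  evidential u on identical clips with audio concepts masked vs complete
  (paired one-sided t-test). The masked pass is exactly invariant to the
  masked activations, so the comparison isolates the graph masking.
* **Personalization**: base trained on a typical cohort (60 infants),
  meta-trained on 40 disjoint heterogeneous infants (expressivity SD
  3.5, 12 clips each, support 5 / query 7), evaluated on 40 fresh
  heterogeneous infants (32 clips each; support = first k clips, query =
  clips 21–32). Uplift = adapted minus unadapted query accuracy, paired
  t-test over infants, at k = 5 and 20.
* **Federation**: the main training split partitioned over 8 sites with
  GA skew (2.1-week between-site spread), pain-event ratios (share of
  level ≥ 2 clips) spread over 15–42%, 3 audio-less sites, and label
  flips mapped from an inter-rater kappa range of 0.68–0.84. FedAvg with
  6-of-8 participation, 20 rounds x 5 local epochs of DP-SGD (clip norm
  1.0, local rate 0.5), validation-plateau stopping (<0.5 points
  improvement for 5 rounds). The noise-free (σ = 0) arm is compared to
  the same SGD on the pooled shards. Privacy accounting composes
  executed Gaussian releases via Renyi DP without subsampling
  amplification, so the reported cumulative ε is a conservative upper
  bound; at the closed-form per-release σ (0.606 at ε = 8, δ = 1e-5) the
  budget is exhausted within the first round, which the simulator flags
  — the closed form budgets a single release, not a 50-round protocol.

## Numerical choices and edge cases

* Strict inequalities everywhere a threshold is compared; exact ties do
  not fire.
* Row softmax excludes self-edges via a −1e9 diagonal offset; masked
  renormalization divides only where row sums are nonzero.
* F0 tracking: FFT autocorrelation on 25-ms frames, peak search in
  150–1000 Hz with parabolic refinement; harmonic-to-noise ratio
  r/(1−r) at the pitch lag, clipped at 20; spectral irregularity is mean
  normalized frame-to-frame power-spectral flux over voiced frames
  (the voicing floor is frame RMS > 0.05).
* SpO2 drops are measured on a 0.5-s smoothed trace (desaturation is a
  sustained event; unsmoothed sample noise inflates the
  max-drop-in-window statistic).
* Degenerate inputs: QWK returns 1 when the weighted expected matrix is
  zero (identical constant sequences); empty calibration bins contribute
  0; an all-abstained evaluation reports coverage 0 with undefined
  metric markers; fewer than 2 physio samples, sub-2048-sample
  waveforms, empty support sets, and all-masked graphs raise typed
  errors.
* Sub-10-s recordings produce zero clips and a logged warning, not an
  exception.

## Known limitations

* The trainable stack is pure numpy on a small tape-based autodiff
  engine; it is adequate for the desk-scale cohorts here but not for
  raw-waveform end-to-end training at scale.
* The default assessment path feeds rule-based concept activations to
  the fusion model; the learned concept heads are trained only through
  the concept-supervision loss and are not the default inference path.
* Per-infant adaptation can express global severity recalibration and
  concept-mixing changes, but not feature remappings; when heterogeneity
  destroys information (e.g. fully saturated facial channels) no 5-shot
  correction exists, and uplift comes from the meta-learned operating
  point rather than support-set fitting.
* The 18-rule base beyond the canonical cross-modal exemplar is package
  configuration, authored against the concept vocabulary and
  sanity-checked on synthetic cohorts; it is meant to be overridden from
  a site's own rules file.
* Federated simulation is statistical only: no transport security,
  secure aggregation, or anomaly rollback (logged no-ops).
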