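# Methods

## Pipeline model and assumptions

The pipeline turns a time-stamped word stream into per-volume class labels
and decodes them from multi-voxel activity:

1. **Sentence reconstruction.** Word annotations (token, onset, offset in
   seconds) are grouped into sentences at explicit end-of-sentence flags or,
   alternatively, at terminal punctuation on tokens. In the original
   workflow this segmentation was done by hand while watching the movie;
   supporting both conventions makes that manual step reproducible. A
   sentence's duration is first-word onset to last-word offset, so
   inter-word silences inside a sentence count toward it. Decreasing onsets
   are tolerated with a warning (real annotation files contain jitter);
   ties are broken by file order.

2. **Lexicon scoring.** compound = S/√(S² + α) with α = 15, where S is the
   signed sum of lexicon valences; a lexicon hit preceded within 3 tokens by
   a negation word is scaled by −0.74. α and the negation factor follow the
   conventions of the lexicon-analyzer family this scorer mirrors; both are
   configurable on the `Lexicon`. Capitalisation and punctuation intensity
   boosts are *not* modelled — no closed form is available for them, and the
   compound score's documented properties (odd under valence negation,
   bounded in (−1, 1), sign-preserving) hold without them. A compound of
   exactly zero is neutral; any nonzero value takes its sign. Third-party
   analyzers plug in through a registry and return polarities in the same
   {−1, 0, +1} encoding; none is required by any other operation.

3. **TR alignment.** Volumes are half-open [t, t + TR) windows, 0-indexed
   from `t_start`. A sentence claims ⌈duration/TR⌉ volumes (tolerance 1e−9
   absorbs float representation error so an exactly-integer ratio is never
   rounded up) starting at floor((onset − t_start)/TR) — the volume
   containing the onset; where the onset convention was ambiguous this
   floor-of-onset rule is fixed and exposed in config. Gap volumes carry the
   previous label (`carry_previous`; `neutral` available for sensitivity
   analysis), pre-first-sentence volumes backfill from the first sentence
   (`neutral` available), and overlapping claims resolve last-writer-wins in
   onset order, matching a single sequential pass. No hemodynamic-lag shift
   or HRF convolution is applied — labels are aligned to stimulus time, an
   acknowledged approximation of the decoded signal's timing.

4. **ROI features.** A voxel belongs to a sphere when its center, mapped to
   mm through the image affine, is within the radius (boundary inclusive,
   tolerance 1e−9). This center-in-sphere convention is the simplest
   discretisation that an exhaustive distance scan can verify; seeds are
   not rounded to the grid. The reference configuration names six regions
   (L_ACC, R_STG, L_cere, L_medFG, R_IFG, L_ch) with voxel counts
   19/20/20/20/16/16 = 111 at 5 mm radius; actual MNI seed coordinates are
   study-specific and must be user-supplied. A TSV bypass accepts
   pre-extracted per-ROI matrices so the decoding half runs without NIfTI
   input.

5. **Balancing.** Random oversampling duplicates minority rows uniformly
   with replacement; SMOTE interpolates x + u·(z − x) between a minority
   point and one of its k = 5 nearest same-class Euclidean neighbours
   (k capped at class size − 1; classic SMOTE, no borderline variants).
   Balancing is applied to the whole dataset *before* splitting by default,
   mirroring the procedure whose results this package operationalises.
   That ordering leaks duplicated rows across the train/test boundary and
   inflates ROS accuracy — the synthetic recovery experiment reproduces the
   effect (≈0.83 "accuracy" at zero signal under ROS). The leakage-free
   variant (balance the training partition only) is available and is what a
   new study should use.

6. **Decoding.** rf/svm/dt run with pinned library defaults (100 trees /
   gini; RBF, C = 1, gamma = scale; gini) recorded into every report so
   "default" survives library upgrades. The MLP uses hidden layers
   [100, 90, 70, 50, 30, 20, 10], ReLU, Adam, logistic output with binary
   cross-entropy for two classes and softmax with sparse categorical
   cross-entropy for three; epochs 50, batch 64, learning rate 1e−3 were
   fixed here as unstated-elsewhere defaults. Features are standardised to
   zero mean/unit variance before SVM and MLP. The 10% validation partition
   is reserved for MLP early stopping and otherwise unused. Aggregate
   precision/recall/F1 are macro-averaged — a pinned choice, symmetric
   across the balanced-data experiments that dominate; k-fold metrics come
   from the pooled confusion matrix across folds.

## Synthetic data: what it emulates and what it does not

`gen_annotations` draws sentence lengths and durations from truncated
log-normals matched to the observed corpus moments (length 6.05 ± 4.81
words, duration 3.8 ± 5.5 s; log-normal chosen because only moments, not a
family, are known), with class priors 0.45/0.22/0.33 (positive/negative/
neutral) matching the positive-heavy mix of a romantic-comedy dialogue
track. Sentences are built constructively — valence-free filler words plus
one to three lexicon words of the target sign — so the internal scorer
recovers the stored polarity exactly, which is what makes end-to-end
identifiability testable.

`gen_fmri_subject` emits x_t = μ_class(t) + ε with one fixed random pattern
per class, drawn once per dataset from a unit Gaussian and scaled to
‖μ_c‖ = d in noise-sd units; noise is iid Gaussian or AR(1)
(x_t = ρx_{t−1} + √(1−ρ²)ε_t, stationary unit variance). There is no
hemodynamic response, physiological noise, motion, spatial autocorrelation,
or inter-subject variability in the patterns. Passing tests therefore show
that the *pipeline machinery* is correct — labels propagate, features are
extracted faithfully, decoders recover separable signal and sit at chance
without it — not that real fMRI carries decodable sentiment at any
particular accuracy.

## Benchmark problem sizes

The test suite and acceptance script run at desk scale as the package's own
benchmark configuration: recovery experiments use 2 subjects × 400 volumes
× 111 voxels; chance-level controls average a random forest over 10 seeds
at 600 × 20; hold-out-vs-k-fold stability uses 1000–2000 rows × 30–111
features over 3–5 seeds. Full-study dimensions (20 subjects × 1744 volumes)
are exercised for bookkeeping (matrix shape 34,880 × 112), not for
training. The headline accuracies reported on real movie-watching data are
not reproducible from synthetic inputs: they depend on the actual fMRI
recordings and the manually constructed sentences.

## Numerical choices and degenerate inputs

- Ceil/floor computations use a 1e−9 relative tolerance against float
  representation error (0.1 × 3 claims 3 volumes, not 4).
- Zero-duration sentences claim one volume (they were spoken, so they
  occupy the volume containing their onset).
- Empty or fully out-of-lexicon sentences score compound 0 → neutral.
- Sphere membership is boundary-inclusive with 1e−9 slack; an empty sphere
  is an error naming the ROI rather than a silent empty feature block.
- SMOTE with two identical minority points degenerates to duplication
  (zero-length segment); singleton minority classes are rejected with a
  pointer to random oversampling.
- Balanced input passes through both oversamplers unchanged.
- All randomness flows through named integer seeds
  (`split_seed`, `balance_seed`, `model_seed`, `shuffle_seed`); the same
  seeds give bit-identical oversampling and identical rf/dt/svm reports.

## Known limitations

- The lexicon scorer omits intensity heuristics (capitalisation,
  punctuation, degree modifiers), so its absolute compound values differ
  from full lexicon analyzers even where signs agree.
- Stimulus-time alignment ignores hemodynamic delay; decoders see labels
  shifted relative to the underlying neural response in real data.
- Default pre-split balancing is faithful to the procedure it
  operationalises but optimistic; use `balance-train-only` for unbiased
  estimates.
- The bundled 50-word demo lexicon is for tests and examples; real analyses
  should supply a published valence lexicon via `Lexicon.from_tsv`.
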