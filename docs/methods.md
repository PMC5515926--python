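# Methods

## Problem and model

MMP substrate-cleavage site prediction is cast as binary classification
of 16-residue windows P8…P1|P1′…P8′ around every peptide bond of a
substrate. Windows whose P1 position carries an experimental cleavage
annotation are positives; all other bond positions are negative
candidates. The predictor is an ε-support-vector regression with RBF
kernel trained on +1/−1 labels; its continuous output is thresholded
(default cutoff 0) into a cleavage call, so the same model yields both a
ranking (for ROC/AUC) and hard calls (for sensitivity, specificity,
accuracy, F-score, MCC).

The transfer-learning protocol addresses proteases with too few
annotated sites for stand-alone training. With one protease designated
the target, the windows of every *other* protease are pooled as the
source domain, and mRMR selects the top `m_common = 50` features there —
the *common knowledge*. The target's own top `m_target = 100` mRMR
features are appended after the common features with duplicates removed
(common first). Forward selection then trains an SVR on every prefix of
this candidate list and records its mean stratified 5-fold CV AUC; the
shortest prefix attaining the maximum is the final feature set, refitted
on all target rows. The merged-data baseline uses plain top-100 mRMR on
the union of all proteases' windows with no source/target distinction.

Assumptions worth keeping in mind: transfer helps only insofar as
cleavage preferences are genuinely shared across proteases; the SVR
sees standardized features (per-training-fold statistics, so held-out
rows never leak into the scaler); and the candidate list is built from
the full target sample, which makes cross-validated AUC of the selected
subset mildly optimistic (see *Selection bias*, below).

## Preprocessing parameters

- **Redundancy reduction** — greedy longest-first clustering at 70%
  global identity (identity = matches / alignment length under
  match = 1, mismatch = 0, gap = −1). This reproduces the intent of
  word-filter clustering tools without an external binary; an external
  cluster file can be honored instead by pre-filtering substrates.
- **Negative sampling** — ratio 3 negatives per positive, drawn without
  replacement, deterministic given a seed. With an accessibility
  profile, buried-P1 candidates ('b') get sampling weight 3 vs 1 for
  exposed, quantifying the rule that buried residues make the most
  reliable negatives; without profiles sampling is uniform. When fewer
  than 3× candidates exist, all are kept and the dataset is flagged.
- **Window padding** — terminal overruns are padded with 'X'. Pads
  encode as the non-standard slot (Binary), the X row (BLOSUM62), the
  per-index mean (AAindex), and are excluded from composition counts
  (AAPair, CKSAAP — N_Total is reduced per the pairs actually present)
  and from CHARGE-Hyd segment means.

## Encoders

Dimensionalities are contractual: AAindex 16×64 = 1024, AAPair 20,
Binary 16×21 = 336, BLOSUM 16×21 = 336, CHARGE-Hyd 3×3 = 9, CKSAAP
6×400 = 2400, DISOPRED 16, PSSM 16×20 = 320; concatenation 4461.

- The bundled AAindex table (`data/aaindex64_synthetic.tsv`) is a
  synthetic stand-in: 64 z-scored pseudo-indices generated once with a
  fixed seed. Curated physicochemical index selections are
  publication-specific; any user table with the same layout (rows =
  indices, columns = 20 residues) drops in, and a table with n ≠ 64
  indices changes the block dimension to 16×n.
- CHARGE-Hyd is property × segment: {mean net charge, aromatic
  fraction, charge:hydrophobicity ratio} × {full window, P8–P1 half,
  P1′–P8′ half}. Charges K,R = +1, D,E = −1, H = +0.1; aromatics
  F,W,Y,H; hydrophobicity is the Kyte–Doolittle mean, shifted by +5.0
  in the ratio's denominator to keep it positive. All scales are
  arguments.
- PSSM log-odds are squashed by the logistic 1/(1+e^−x) so features lie
  in (0,1); missing rows and pad slots impute 0.5 (the squashed zero
  score). DISOPRED probabilities impute 0.5 likewise. These fills keep
  profile-free operation well defined rather than silently failing.

## mRMR

The MID (difference) variant: first pick maximizes relevance I(f;y);
each later pick maximizes I(f;y) − mean_{s∈selected} I(f;s). Mutual
information is the plug-in estimate in bits on discretized columns:
columns with ≤ 2 distinct values are already discrete and pass through
as codes (this covers one-hot features; note a two-valued balanced ±1
column sits exactly at μ±σ, where threshold binning would destroy it),
all others are cut into 3 states at mean ± one standard deviation. Ties
break toward the earlier column, making the ranking deterministic and
row-order invariant. Internally, joint counts are computed as one
dense matrix product against a precomputed state-indicator matrix; a
unit test pins this to the naive per-pair formula.

## SVR and grid search

Defaults follow LibSVM conventions: ε = 0.1, grid c ∈ {2⁻⁵…2¹⁵},
γ ∈ {2⁻¹⁵…2³}, both in ×4 steps; ties in mean CV AUC resolve to the
smallest c, then the smallest γ. Folds are stratified and seeded; when a
class has fewer members than folds (e.g. leave-one-out on toy data)
plain K-fold is the documented fallback. By default the grid search
runs once per target on the full candidate list and the winning (c, γ)
is reused for every prefix; `per_prefix_grid` restores the stricter
(and far slower) per-prefix protocol. Benchmark runs in
`mmptl.experiment`, the CLI default, and the tests use a compact 3×3
grid (c ∈ {0.5, 8, 128}, γ ∈ {2⁻⁷, 2⁻³, 2}) spanning the mid-range of
the full grid — a problem-size choice for single-CPU runs; `--full-grid`
restores the complete search.

## Evaluation

AUC is the Mann–Whitney statistic (ties ½), identical to the trapezoidal
area under the empirical ROC curve. Two F-scores are reported: the
standard F1 = 2TP/(2TP+FP+FN) as the headline value, and the variant
2TP/(2TP+FP+TN) that appears in some printed formula listings, kept for
comparability. Any zero-denominator metric is reported as NaN with an
explicit `undefined` flag, never silently as 0. Cross-validation pools
held-out scores for the AUC and reports threshold metrics both pooled
and per fold; reporting folds are freshly seeded (selection seed + 1) so
the forward-selection folds do not grade themselves.

## Cleavage entropy

Per window position, S_i = −Σ_a p_a(i) log₂ p_a(i) over the 20 standard
residues with plug-in frequencies from the positive windows only, pads
excluded; maximum log₂20 ≈ 4.32 bits. Low entropy means stringent
positional specificity. Because heat-map color conventions for this
quantity differ between sources, the profile also exposes the inverted
specificity score log₂20 − S_i and a normalized variant S_i/log₂20, so
either orientation can be reproduced. The raw positional counts are
exportable for sequence-logo plotting.

## Synthetic scenarios

`default_mmp_like_spec` builds 5 source domains + 1 target. Per-domain
sizes are drawn uniformly within the ranges typical of curated MMP
substrate sets — 23–44 substrates and 85–290 cleavage sites per
protease, substrate lengths 150–400 — and each planted window is
sampled per position from strength·preference + (1−strength)·background
(uniform background by default; preference weights summing to < 1
spread their remainder over unlisted residues). The shared motif is G at
P7, P4, P1, P3′, P6′, P at P3, P5′, and L at P1′; every domain adds two
private preferred positions so source and target differ beyond the
shared signal. Default strength 0.6. Sites are placed with ≥16-residue
separation via the exact gap-removal bijection, so placement is uniform
over admissible configurations and fully deterministic given the seed.

What passing tests on this generator do **not** show: robustness to
real substrate homology (sequences here are i.i.d.), to the natural
residue background, to annotation noise in curated databases, or to
imperfect upstream predictors — synthetic PSSMs are motif-derived
pseudo-counts and synthetic disorder/accessibility are uninformative
noise, all labelled as such. Published benchmark figures on curated
substrate data therefore cannot be reproduced here; the test suite
instead checks the method's definitional arithmetic exactly and its
learning behavior on planted signal.

## Selection bias and the null control

Because mRMR ranking and forward selection see the full target sample,
cross-validated AUC of the chosen subset retains optimism even when no
signal exists: at strength 0 the CV AUC sits around 0.6–0.75 rather
than 0.5. The unbiased null measurement is the AUC of the final model
on an *independently generated* scenario with strength 0, which
concentrates at 0.5; `scripts/acceptance.py` reports both numbers
(`null_transfer_cv_auc`, `null_independent_auc`) so the gap is visible
rather than hidden.

## Benchmark problem sizes

The acceptance script and the recovery test use the Binary + CKSAAP +
AAPair encoders (2756 features), the compact grid above, 3–10 seeded
replicates, and the default scenario scale (~1000 target windows after
1:3 sampling). These are the package's standard benchmark conditions;
all of them widen through ordinary function arguments.

## Known limitations

- The greedy identity clustering is O(n²) alignments; for thousands of
  substrates an external clustering tool's output should be supplied
  instead.
- Grid search once-per-target (the default) can pick hyperparameters
  that are mildly suboptimal for short prefixes.
- The bundled AAindex table is synthetic; for physicochemical
  interpretability a curated table must be supplied.
- `f_score_as_printed` is not a standard metric and should not be
  compared against F1 values from other software.
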