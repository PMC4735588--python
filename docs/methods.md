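# Methods

## Study design being modelled

The package analyses a two-phase, paired cohort: each relapsing-remitting
multiple sclerosis patient contributes one blood sample during a relapse and
one during remission, alongside age/sex-matched healthy controls sampled
once. Expression is measured at probe level on an sncRNA array (miRNA and
snoRNA probes) as log2 intensities with per-probe, per-array
detection-above-background calls. Because the disease is strongly
female-predominant and sex effects pervade its transcriptome, every contrast
is run in three strata — all samples, females only, males only — and the
relapse-vs-remission contrast is run paired, restricted to patients treated
identically in both phases.

## Preprocessing

Detection calls are consumed as booleans; when only detection p-values are
available, `detection_calls` thresholds them (default p < 0.05). The filter
retains human probes detected in at least one array. The retained percentage
is reported truncated to two decimals (1113 of 1769 probes → 62.91%).

Quantile normalization forces every sample onto the common distribution
defined by the row means of the column-sorted matrix. Tied values within a
column receive the mean of the quantile values their block spans. On
continuous data the transform is exactly idempotent; with ties a second
application can perturb tied entries slightly because the tie blocks feed
back into the reference distribution — ties are measure-zero for real
intensities, so this is immaterial in practice. The pipeline's default order
is detect → normalize → filter (the full matrix is normalized, then
undetected/non-human probes are dropped); the stages are independent
functions, so any other order can be composed.

## Rank-product differential expression

For a two-class contrast the ratio matrix has one column per comparison
unit: per patient (class-a minus class-b log2 values) for paired designs,
or per class-a × class-b sample pair for unpaired designs, always with
class b as the reference so positive ratios mean higher expression in
class a. Within each column probes are ranked (ascending ratios for the
"down" direction, descending for "up"; ties get average ranks, so each
column's ranks always sum to n(n+1)/2), and the rank product is the
geometric mean of a probe's ranks across columns.

The null distribution is generated by permutation:

* **Paired designs** shuffle probe labels independently within every ratio
  column, preserving each column's rank multiset. Columns belong to
  different patients and are independent, so this matches the data's
  dependence structure.
* **Unpaired cross-pair designs** shuffle probe labels within every
  *original sample* and rebuild all cross-pair columns. This is essential:
  ratio columns sharing a sample are strongly correlated (a probe's
  measurement error in one sample enters every column that sample forms),
  and a within-ratio-column shuffle destroys that correlation and
  understates the null tails — in our checks it declared roughly a quarter
  of all probes significant on a cohort with 5% planted effects. The
  sample-level scheme reproduces the shared-sample correlation in the null
  and restores calibration.

From the pooled permuted rank products we report, per direction:
`p_perm(g) = (1 + #{RP_perm ≤ RP_obs(g)}) / (1 + N_perm · n_probes)`,
`E[FP](g) = #{RP_perm ≤ RP_obs(g)} / N_perm`, and
`pFP(g) = E[FP](g) / rank(g)` — the expected proportion of false positives
among the probes called at g's rank — capped at 1 and monotonized by a
cumulative minimum from worst to best rank product, which makes thresholding
well defined. A probe is significant when p_perm ≤ 0.001 and pFP < 0.05 in
at least one direction; under the complete null the p-values are uniform,
while the *declared* fraction at pFP < 0.05 is near zero, which is the
correct behaviour of an FDR-controlling quantity (the nominal rate bounds
the false fraction *among declarations*, not the declaration rate).
Defaults: 1000 permutations, mandatory seed; negating every ratio swaps the
up and down results exactly.

## Mirror-pattern analysis

The shared signature is the intersection of the significant sets of the two
phase-vs-control contrasts. Each shared probe is labelled *opposite* when
its control-referenced log2 fold changes in the two phases have strictly
opposite signs; a zero fold change counts as concordant, which is
conservative toward the mirror claim. The concordance null is the minimal
one: each shared probe is opposite with probability ½ independently, tested
one-sided toward excess opposition with the exact binomial tail
p = Σ_{i≥k} C(n,i)(½)ⁿ. Eight opposite of eight shared gives 0.00390625
(0.004 at three decimals); eight of ten gives 0.0546875. Percentages are
reported rounded half-up to the integer. `compare_lists` provides the
related set operation for comparing two direction-labelled lists (e.g.
in vivo vs cultured-cell experiments), partitioning their union into
same-direction, opposite-direction and exclusive sets.

## Target network

Prediction records (miRNA, gene, number of predicting source algorithms,
0–100 integrated standard score) pass three order-commuting filters:
n_sources ≥ 3 and score ≥ 40 (both inclusive, the plain reading of
"minimum"), and target membership in a supplied blood-expressed gene list —
supplied, not re-derived, so the pipeline stays database- and
platform-version independent. The biological filter then keeps only records
whose miRNA and target log2 fold changes have strictly opposite signs
(miRNAs predominantly repress their targets); zero or missing fold changes
drop the record. Raw signed fold changes are used without a significance
gate. Duplicate (miRNA, gene) rows collapse to one edge keeping the maximum
score and source count. The resulting directed graph is bipartite by
construction (validated), with node kind miRNA/TF/gene, GWAS flag,
fold change and degree, and weakly connected components counted.

## Enrichment

Plain per-term over-representation: upper hypergeometric tail
P(X ≥ overlap) with the blood-expressed list as both background and sampling
frame for the query (network genes), terms intersected with the background
before testing, Benjamini-Hochberg across all tested terms, significance at
q < 0.05. Term-grouping/fusion heuristics of ontology browsers are
deliberately out of scope; gene sets arrive as GMT input.

## qPCR

Replicate CTs collapse to their mean, flagged when the replicate SD exceeds
0.5 cycles. ΔCT subtracts the arithmetic mean CT of the sample's endogenous
controls (equivalent to the geometric mean of their expression — the
standard dual-control rule); ΔΔCT contrasts group-mean ΔCTs against the
reference group and fold = 2^−ΔΔCT, so the reference fold is exactly 1 and
any constant shift of a sample's CTs cancels. Cross-platform concordance is
Pearson's r between array and qPCR log2 fold changes (per-group fold
changes; a per-sample variant is a straightforward extension). Group
comparisons run Shapiro-Wilk at α = 0.05 on each group (on the differences
when paired) and choose the t-test when normal, otherwise the Wilcoxon
signed-rank (paired) or rank-sum (unpaired) test; degenerate
zero-variation inputs report p = 1 deterministically.

## Synthetic cohort generator

Log2 intensity = probe baseline ~ N(8, 2) + patient effect ~ N(0,
patient_sd), shared by a patient's two samples + planted effect + residual
N(0, noise_sd); detection call = intensity > detect_floor. Planted effects
shift designated probes by ±effect_log2 in a designated stratum and phase
relative to controls; mirror probes get +e in one phase and −e in the
other. Planted DE miRNAs each repress three invented genes whose log2 fold
changes take the opposite sign (the stand-in for the companion mRNA
experiment); prediction tables mix these true pairs (n_sources ∈ {3..12},
score ∈ [40, 100] — all pass the filters) with decoys (n_sources uniform on
{1..12}, score uniform on [0, 100] — a known fraction fails each filter).
qPCR plates draw per-sample loading offsets N(0, 0.5) that cancel in the
control subtraction and replicate noise N(0, ct_sd), so 2^−ΔΔCT recovers
the planted fold exactly at ct_sd = 0. Gene-set collections plant one term
equal to a designated query subset among uniform decoy terms.

Defaults mirror the modelled study: 24 patients + 24 controls, 1769 probes
(48% miRNA), sex ratio 0.72, planted DE counts 38 (female relapse), 42
(female remission), 7 (male remission) with 8 mirror probes. effect_log2
defaults to 1.5 — a calibration choice, since real effect magnitudes are
probe-specific; patient_sd = 0.7 and noise_sd = 0.5 give realistic
between-subject dominance. Tests and examples use 120–500 probes and
150–1000 permutations, sizes at which every statistical property under test
(calibration, recovery, oracle agreement) is already stable. What the
generator deliberately omits: probe-level array physics, cross-
hybridization, batch effects, correlated probe blocks, and treatment
heterogeneity (every simulated patient keeps one treatment across phases) —
so passing tests demonstrate the correctness and calibration of the
*methods*, not the effect sizes to expect from real cohorts.

## Numerical choices and degenerate inputs

Seeds are mandatory anywhere randomness enters; derived stage seeds are
small fixed offsets of the run seed, and identical config + seed reproduce
byte-identical reports. p_perm has floor 1/(1 + N_perm·n_probes); direction
assignment prefers the uniquely significant direction, then the smaller
rank product. A constant ratio column yields all-average ranks and is
handled by the tie rule. Comparisons resolving to fewer than two ratio
columns raise (the pipeline logs and skips such strata); patients missing
one phase are excluded from paired designs with a warning. The
fold-change filter reads "beyond twofold" strictly (FC = 2.0 excluded).

## Known limitations

The permutation count of the original interactive tooling is unreported;
1000 is the package default and the p-value floor scales accordingly. The
sign test assumes exchangeable, independent shared probes; co-regulated
sncRNA clusters would violate independence and make the p-value
anti-conservative. Enrichment results depend entirely on the supplied GMT
collection. The qPCR module models perfect amplification efficiency (the
2^−ΔΔCT assumption) and does not implement standard-curve correction.
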