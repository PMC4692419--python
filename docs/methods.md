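# Methods

## Phenotype model

CIPN status is a deterministic function of the FACT-Ntx trajectory: with
baseline score `b` (integer, 1–44) and follow-up score `f`, the fractional
worsening is `(b − f) / b`; a patient is group 1 (CIPN) iff the maximum
worsening over the available follow-ups (completion, month 6, month 12) is
≥ 0.20, with the boundary inclusive. Design choices at the edges:

* A baseline of 0 makes percent change undefined; it is rejected for manual
  review rather than treated as infinite worsening.
* Missing intermediate follow-ups are allowed (the rule quantifies over
  whichever follow-ups exist), but a patient with *no* follow-up is an
  error, never silently "stable".
* Cohort summaries report percentages to 2 d.p. with the group size as
  denominator; raw values are kept internally. Because prose and tables of
  small-cohort reports sometimes disagree about mean vs median, the summary
  emits mean, SD and median for the continuous variables.

## Identification model

Digestion is fully tryptic: cleavage C-terminal to K or R, suppressed
before proline (the default convention of common search engines; the
suppressed-KP rule is a package choice, exposed alongside a configurable
missed-cleavage count of 0–2, default 0, and a minimum peptide length of 7).
Proteins whose digests are indistinguishable are merged into groups whose
accession is the sorted ';'-join of the members, so grouping is
deterministic; uniqueness of a peptide is defined against groups. I and L
are distinct residues by default (`equate_il` merges them).

Decoys are whole-sequence reversals, tagged `DECOY_`. The PSM FDR at score
threshold `t` is `#{decoy, score ≥ t} / #{target, score ≥ t}` — the simple
ratio estimator, appropriate when the decoy population is matched one-to-one
to the incorrect-target population. Filtering picks the smallest observed
score with estimated FDR ≤ α (α = 0.05 by default), which maximises the
accepted-target count; ties at the threshold are all accepted, and an
unattainable α yields an empty set with a warning rather than an exception.
FDR is computed at PSM level (the accepted PSMs feed spectral counting) in
a single pass over the pooled table of all technical replicates; replicate
merging afterwards sums PSM counts and peak areas and keeps the best score
per (sample, timepoint, peptide, charge), refusing duplicate spectrum ids
within a replicate run.

## Quantification

* Protein track: integer matrix of unique spectral counts. A PSM
  contributes to exactly one protein group (its peptide's sole owner) or to
  none (shared peptides are excluded rather than fractionally allocated —
  exclusion is the simplest rule with zero duplication).
* Peptide track: real matrix of peak areas per unique peptide, summed over
  charge states (one peptide = one feature).
* Missing feature-in-sample values are zeros, not NA — spectral counting
  has a natural zero and the rank test tolerates ties at zero. All-zero
  rows are dropped (with a logged count).
* Peptide-track results are rolled up to proteins by best evidence: a
  protein is reported iff ≥ 1 unique peptide passes, with protein
  q = min(peptide q). Min-q overstates per-protein confidence slightly (no
  multiplicity correction across a protein's peptides); it is used only for
  membership of the expanded signature, never as a calibrated protein-level
  FDR.

## Statistics

Normalization is per-sample library-size scaling — every column is scaled
so its total equals the median column total — followed by ln(x + 1). This
removes depth (injection/loading) differences and compresses the dynamic
range ahead of a rank test and PCA. It does not correct compositional
effects: when most true changes point one way, scaling slightly shifts all
other features the other way. The effect is visible in the simulation as a
false-positive excess whose direction opposes the planted majority, and is
one reason selection error is controlled at a generous 20–30% FDR rather
than 5%.

The per-feature test is the two-sided Mann–Whitney U. The exact null
distribution is used whenever the pooled values are tie-free and the
combined size is ≤ 30 — at the study's 8 vs 9 this is C(17,8) = 24,310
arrangements, cheap to evaluate — otherwise the normal approximation with
tie-corrected variance and continuity correction. Fully degenerate input
(all values equal) is flagged and reported as p = 1, U = n₁n₂/2. Both modes
are also selectable explicitly; tests verify the exact mode against a
brute-force enumeration oracle and the asymptotic mode only through its
conservative behaviour, because with heavy ties there is no exact reference
without a permutation test.

Benjamini–Hochberg adjustment is applied separately per track and per
timepoint (the two tracks are reported separately, implying separate
adjustment), via the standard step-up `q(i) = min_{j ≥ i} m·p(j)/j` capped
at 1. Selection is strict (`q < 0.2`, `q < 0.3`).

Direction of change is the comparison of group medians on normalized
values (robust, consistent with the rank test); equal medians are "tied".
For combined-signature members found only by the peptide track, direction
falls back to the best peptide's direction.

PCA is computed on feature-centered (not variance-scaled) normalized
values; the separation index is the distance between group centroids in
the 2-D score space divided by the mean distance of samples to their own
group centroid. Rank-1 data fall back to a 1-D projection with a warning;
identical samples are an error; zero within-group spread returns infinity.

## Synthetic data generator

The generator emulates the study design: 8 CIPN + 9 stable patients, serum
at T0 and T12, 3 technical replicates, 800 detectable proteins, 12
differential proteins at a 4-fold effect with 32/37 of effects elevated in
the stable group. Specifics and defaults:

| knob | default | why |
| --- | --- | --- |
| `mean_psms_per_protein` | 10 (merged, per sample) | sparse, tie-heavy counts typical of single-shot serum exosome runs at ~800 identified proteins, while keeping multi-seed studies tractable |
| `abundance_sigma` | 0.8 (ln-scale) | moderate spread; real serum spans far more orders of magnitude, but extreme spread would push most proteins below detectability |
| `count_dispersion` | 0.1 (NB, var = μ + dμ²) | asymptotic count CV ≈ 0.32, in line with technical-replicate-merged label-free counts with moderate biological variation; Poisson is the d → 0 limit |
| `depth_cv` | 0.20 | per-run log-normal depth factor emulating injection/loading variability — the nuisance library-size normalization exists to remove; without it, raw-count ties break in a systematically group-ordered way and normalization artifacts dominate the false positives |
| `area_cv` | 0.30 | peak-area measurement CV around abundance |
| `decoy_score_shift` | 3.5 SD | correct-target scores N(3.5, 1) vs incorrect/decoy N(0, 1): clean but not perfect separation, so the 5% FDR threshold does real work |
| `incorrect_target_fraction` | 0.10 | plausible pre-filter PSM error rate; decoy counts are drawn from the same binomial law so the decoy estimate is calibrated by construction |
| `shared_peptide_fraction` | 0.10 | a minority of proteins carry one peptide copied from another protein, exercising the uniqueness logic |

Differential proteins are drawn from the upper half of the abundance
distribution: a 4-fold change on a protein seen in a fraction of a
spectrum per run is invisible to *any* method at this depth, and the
planted effects are meant to model detectable biomarkers. Effects are
planted at both timepoints. Trajectory scores are resampled (never
clamped) until integer rounding reproduces the planted group label, and
demographics are drawn from the per-arm category frequencies of the study
cohort. With `effect_log_fold = 0` the ground-truth differential set is
empty, giving a clean null.

All randomness derives from the single config seed through fixed-purpose
seed sequences (cohort/proteome/PSMs), so equal configs give byte-identical
output files, and each stage is independently reproducible.

What the generator does **not** model: retention time or spectra (no mzML),
protein-correlated peptide detectability (peptides of one protein are drawn
uniformly), batch effects, missingness mechanisms other than sampling
zeros, score distributions with realistic shape (Gaussians suffice to
exercise threshold logic, not to model a real discriminant), or
inter-protein abundance correlation. Passing recovery tests therefore shows
the pipeline's logic and error control are correct under the stated
stochastic model — not that the real study's specific protein lists would
be reproduced, which additionally depend on raw spectra and a proprietary
normalization.

## Problem sizes used in validation

The end-to-end recovery study runs the full default condition (800
proteins, 12 planted effects, 8 vs 9 patients, ~300k PSM rows per dataset)
over 100 seeds in the test suite and 25 seeds per arm in the acceptance
script, reporting medians across seeds. With strong planted effects, the
median protein-track sensitivity at q < 0.3 is expected near 1, and the
median false-discovery proportion sits near the Benjamini–Hochberg design
level q·m₀/m ≈ 0.295 — BH controls FDR at, not below, its nominal level
when p-values are well calibrated, so values just under 0.3 indicate
correct, not marginal, behaviour.

## Known limitations

* Peptide-level q-values roll up by minimum, so the expanded peptide-track
  protein list is anti-conservative at the protein level.
* Library-size scaling leaves compositional bias uncorrected (see above);
  a median-of-ratios scale factor would be the natural upgrade but would
  change the stated normalization.
* The asymptotic Mann–Whitney branch is approximate for the heavily tied,
  zero-inflated low-abundance features; at n = 17 the approximation is
  conservative in the far tail, which costs a little sensitivity for rare
  proteins.
* The cohort summary does not perform significance tests across arms (the
  study sizes make them uninformative), only descriptive arithmetic.
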