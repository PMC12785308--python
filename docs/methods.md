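# Methods

`trichostudy` re-implements, as a reusable toolkit, the computational core of
a diagnostic reader study in which dermatologists of three experience levels
and four general-purpose multimodal language models each diagnosed the same
set of trichoscopic images. Three concerns drive the design: (i) images shown
to pretrained models must be perturbed enough to defeat memorisation without
destroying diagnostic morphology; (ii) responses must be scored and
summarised with proportion CIs, contingency tests and chance-corrected
agreement; (iii) everything must be reproducible from seeds, because the
original study's images and raw responses are not public.

## Anti-leakage transform pipeline

Ten stages run in a fixed order on 8-bit RGB images:

1. **Crop** `crop_fraction_per_side` (default 0.0075) of each dimension from
   each of the four sides.
2. **Pad** a uniform frame of `pad_fraction` (default 0.015, white) per side.
3. **Scale** by a factor drawn uniformly from `scale_range` (default
   0.90–1.10), bilinear, canvas resized.
4. **Rotate** by an angle from `rotation_range_deg` (default −3° to +3°)
   about the centre, canvas kept, corners filled with the pad colour so they
   blend into the padding frame.
5. **Brightness** — multiply all channels by a factor from 1.01–1.04.
6. **Contrast** — scale deviations from the *per-image mean* by 1.01–1.04.
   Pivoting on the image mean rather than mid-gray makes a factor near 1 a
   near-identity at any exposure.
7. **Saturation** — scale chroma about the per-pixel BT.601 luma by
   1.005–1.01.
8. **Gamma** — `v -> 255 (v/255)^(1/gamma)`, gamma from 0.8–1.2.
9. **Gaussian blur**, odd kernel size (default 3), sigma from the standard
   kernel-size convention `0.3((k-1)/2 - 1) + 0.8`, reflective borders.
10. **Gaussian noise** (default sd 2.0 intensity units) followed by a
    **smoothed perturbation**: a white-noise field smoothed with a Gaussian
    of sd 8 px and rescaled to a maximum absolute value of 3.0 intensity
    units, added identically to all channels.

Values are clipped to [0, 255] after every photometric step; each stage
rounds to 8 bits on output. The noise and perturbation amplitudes are chosen
so the mean absolute pixel change they cause stays below ~2% of the dynamic
range; they are deliberately visible to hashes but not to a reader.

**Pixel rounding.** Fractional pixel counts (crop, pad, scale) round to the
nearest integer with exact ties rounding *down* (`round_px`): 0.75 → 1,
5.91 → 6, 1.5 → 1. One fixed convention keeps the output-dimension
arithmetic closed-form testable.

**Reproducibility.** Every random parameter is sampled from the per-image
seed; the sampled values are returned in a `TransformRecord`, and re-running
with a record reproduces the output bit-exactly. Batch runs derive per-image
seeds by SHA-256 of `(master seed, file name)`, so adding files never
changes existing outputs. Outputs are PNG (lossless) so byte-identity holds.

## Integrity verification

The study's requirement — transformed images stay diagnostically valid for
humans but unrecognisable to models trained on the originals — was confirmed
there by expert review, which cannot be reproduced. The toolkit substitutes
declared metric proxies:

- **Preservation**: mean local SSIM between luma channels, 7×7 Gaussian
  window (sigma 1.5), K1 = 0.01, K2 = 0.03, dynamic range 255, evaluated
  over all fully contained window positions (global statistics below 7 px).
  Unequal sizes are bilinearly resized to the smaller dimensions first.
- **Disruption**: Hamming distance between 64-bit average hashes (8×8
  box-averaged luma thresholded at its mean, strict) and difference hashes
  (8×9 grid, strict left-greater-than-right), the standard near-duplicate
  fingerprints. Box averaging (area mean, computed in float) is used for
  downsampling because it is stabler than nearest-neighbour.

A pair passes when SSIM ≥ `preserve_ssim` **and** at least one hash distance
≥ `disrupt_bits`. The defaults (0.65 and 1 bit) were calibrated on 20 seeded
synthetic scalp images under the default transform config: observed SSIM
ranged 0.64–0.82 (the geometric stages dominate the loss on thin
high-contrast hair strokes) and hash distances were ≥ 2 bits throughout, so
0.65 accepts 19/20 pairs while a pure-noise counterfeit scores ≈ 0 SSIM.
Both thresholds are configuration, not constants.

## Scoring

A response supplies one suspected diagnosis (SD) and up to three
differentials (DD). Under the `SD` rule a cell is correct iff the suspected
diagnosis equals the verified truth; under `SD_DD`, iff the truth appears
anywhere in the set — so SD+DD correctness dominates SD cell-wise by
construction. Labels are canonicalized (lowercase, punctuation/whitespace
collapsed) and passed through an editable synonym vocabulary; matching is
exact after canonicalization. Fuzzy matching is deliberately excluded: it
would inject unauditable judgment into the correctness definition. A missing
suspected diagnosis scores 0 and is flagged. Unanswered (rater, case) pairs
are missing cells, excluded from every denominator.

## Accuracy statistics

Accuracy pools correct cells over evaluations: `p = k/n` with a **Wilson
score interval** — centre `(p + z²/2n)/(1 + z²/n)`, half-width
`z sqrt(p(1−p)/n + z²/4n²)/(1 + z²/n)`. The Wilson interval is the score
test inverted, exact at the k = 0 and k = n boundaries, and is the method
that reproduces every interval printed in the reference study's accuracy
table; the implementation is verified against a grid-search inversion of the
score test for all k ≤ n ≤ 30.

Groups are compared on the correct/incorrect × group table with Pearson's
chi-square (no continuity correction). "When appropriate" is operationalised
as Cochran's rule: if any expected cell is below 5 the test switches to
Fisher's exact (hypergeometric enumeration for 2×2; seeded Monte-Carlo over
100,000 fixed-margin tables otherwise, with the +1 correction on both
numerator and denominator). A significant omnibus test (p < 0.05) triggers
all pairwise 2×2 tests with **Holm–Bonferroni** step-down adjustment
(i-th smallest p multiplied by m−i+1, running maximum, capped at 1).

Evaluations are treated as independent. This matches how such reader studies
are conventionally tabulated but ignores clustering by rater and by case, so
the omnibus p-values are anti-conservative to an unknown degree; a clustered
or mixed-effects analysis is explicitly out of scope.

## Inter-rater agreement

Gwet's AC1 for binary ratings, multi-rater form with missing data: for item
*i* with `r_i ≥ 2` ratings of which `r_i1` are "correct",

    a_i = Σ_k r_ik (r_ik − 1) / (r_i (r_i − 1)),
    p_a = mean a_i,  π = mean (r_i1 / r_i),  p_e = 2π(1−π),
    AC1 = (p_a − p_e) / (1 − p_e).

Items rated by fewer than two of the selected raters are excluded. The
chance term `2π(1−π)` is what keeps AC1 stable under skewed prevalence,
where kappa collapses; it also makes AC1 invariant to swapping the 0/1
labels. Standard errors use a leave-one-item-out jackknife rather than a
closed-form variance: it is assumption-light, naturally handles unequal
`r_i`, and is directly testable (duplicating every item must shrink the SE
by ≈ 1/√2). The CI is `AC1 ± z·SE` truncated to [−1, 1]. Interpretation
bands: < 0 poor, 0–0.20 slight, 0.21–0.40 fair, 0.41–0.60 moderate,
0.61–0.80 good, 0.81–1 very good (upper bounds inclusive).

"Between groups" agreement collapses each group to a per-case majority-vote
pseudo-rater (ties count incorrect — the conservative reading for a
correctness vote) and runs AC1 on the pseudo-raters. This construction is a
declared interpretation: the reference study reports such rows without
describing how they were built, so these values are comparable in spirit
but not validated against it, and the study's own AC1 confidence intervals
cannot be reproduced without its unpublished response matrix.

## Synthetic data: what it does and does not emulate

The generator provides the two inputs the real study cannot share.

*Images*: a skin-toned background with curvilinear hair-shaft strokes
(quadratic Bézier, disk brush, hard pixels — no anti-aliasing, so
brute-force pixel oracles are exact), filled follicular dots, and optional
colour patches. This reproduces what the transform pipeline must preserve
(thin dark curvilinear structure, point structures, colour fields) but makes
no attempt at photorealistic dermoscopy or disease-specific pattern
taxonomies. Integrity thresholds calibrated on these images therefore
characterise the pipeline on *structured synthetic content*, not on clinical
photographs.

*Responses*: a logistic model `P(correct) = expit(group logit + case
offset)` with per-case offsets drawn once from N(0, sd). Group baseline
log-odds default to the reference study's observed per-group SD accuracies
(residents ≈ 0.49, board-certified ≈ 0.51, experts ≈ 0.71; the four models
0.16/0.16/0.33/0.08), the roster defaults to its 5/4/6 + 4 design with 25
cases and one missing model evaluation, and the case-difficulty sd defaults
to 1.0 — enough between-case heterogeneity for agreement statistics to be
exercised away from degenerate values. SD+DD matrices are simulated by
upgrading incorrect SD cells with group-specific rescue probabilities, which
enforces the dominance the scoring rule guarantees. The model has no
rater-level random effect and no rater×case interaction beyond the shared
difficulty, so simulated agreement values are a function of the group means
and difficulty spread, not a reproduction of the study's reported AC1 rows.

A deterministic companion, `matrix_from_margins`, builds matrices whose
margins equal prescribed correct counts (correct cells packed at the lowest
case indices). Margin-determined statistics — percentages, Wilson CIs,
contingency tests — are exact on such matrices; joint-pattern statistics
(AC1) are not meaningful on them and are not computed there.

The default case grid places the single missing evaluation at the last case;
which case was actually missing is unknown, and no margin-determined
quantity depends on the choice.

## Numerical conventions and degenerate inputs

- Seeds: all sub-seeds derive from SHA-256 of `(master, identifiers)`,
  reduced mod 2³¹ — stable across processes, independent per identifier.
- Photometric arithmetic in float64, clipped per step, rounded half-to-even
  once at stage output; identity factors are exact identities on integer
  images.
- A blur kernel of 1, zero noise sd, zero perturbation amplitude, zero
  fractions and collapsed ranges make the whole pipeline the identity.
- SSIM of two constant images follows the closed form
  `(C1)(C2)/((μ²_sum + C1)(C2))`; images smaller than the window fall back
  to global statistics.
- `categorize_ac1` treats each band's upper bound as inclusive; values
  above 1 are rejected, values below −1 cannot arise from the formula.
- Monte-Carlo Fisher uses `(1 + extreme)/(1 + samples)` so p is never 0.

## Problem sizes used in the checks

The self-checks run at sizes chosen to keep the full suite fast while
leaving no statistical ambiguity: 20 image pairs for the integrity
calibration; 1,000 seeded runs for the parameter-range sweep; all k ≤ n ≤ 30
for the Wilson inversion; every 2×2 table with total ≤ 20 for the Fisher
enumeration; 2,000 null replicates (two groups × 100 evaluations at p = 0.5)
for the type-I calibration of `compare_groups`, whose empirical rejection
rate must lie in [3.5%, 6.5%] at the 5% level.

## Known limitations

- Metric thresholds stand in for expert confirmation of diagnostic
  validity; they are calibrated on synthetic content.
- Independence assumptions in the contingency tests (see above).
- The between-group agreement construction is an interpretation, not a
  validated reproduction.
- One cell of the reference margins table is internally inconsistent at the
  printed precision (the experts' SD+DD percentage); the toolkit derives the
  count from the pooled total, as documented in `trichostudy.margins`.
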