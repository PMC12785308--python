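# trichostudy

A toolkit for running and analysing diagnostic **reader studies in
trichoscopy** — head-to-head comparisons where human readers (dermatology
residents, board-certified dermatologists, trichology experts) and
multimodal AI models diagnose the same set of scalp dermoscopy images.

It covers the three computational problems such a study poses:

1. **Anti-leakage image preparation.** Publicly sourced clinical images may
   already sit in a pretrained model's training corpus, so showing them
   unaltered inflates the model's apparent accuracy through near-duplicate
   recognition. A ten-stage seeded transform (crop → pad → scale → rotate →
   brightness/contrast → saturation → gamma → blur → noise → smoothed
   perturbation) perturbs each image enough to shift perceptual hashes while
   preserving diagnostic morphology, and records every sampled parameter so
   any output is reproducible bit-exactly.
2. **Integrity verification.** Each original/transformed pair is scored for
   preservation (mean local SSIM on luma, 7×7 Gaussian window) and
   disruption (Hamming distance between 64-bit average/difference
   perceptual hashes), with configurable pass thresholds.
3. **Statistical analysis.** Responses are scored against verified truths
   under the SD rule (suspected diagnosis only) and the SD+DD rule
   (suspected plus up to three differentials). Accuracy is the pooled
   proportion correct with a **Wilson score 95% CI**
   (centre `(p̂ + z²/2n)/(1 + z²/n)`); groups are compared with Pearson's
   χ² or Fisher's exact test (Cochran's rule), **Holm–Bonferroni**-adjusted
   post hoc; inter-rater reliability is **Gwet's AC1**
   (`AC1 = (p_a − p_e)/(1 − p_e)` with `p_e = 2π(1−π)`), jackknife CI,
   with the usual slight/fair/moderate/good bands.

Because the motivating study's images and raw responses are unpublished, a
first-class synthetic-data module generates scalp-like images with known
ground-truth structures and simulates rater×case correctness matrices under
a logistic group-skill / case-difficulty model, so the entire pipeline runs
and is tested without any external data. See `docs/methods.md` for the full
model descriptions and design decisions.

## Worked example

Rebuild the reference study's accuracy table from its published margins and
test the human-vs-AI contrast:

```sh
trichostudy paper-margins --out margins_out
```

```
          group  mode   k   n  pct  ci_lo  ci_hi
 dermatologists    SD 218 375 58.1   53.1   63.0
       resident    SD  61 125 48.8   40.2   57.5
board_certified    SD  51 100 51.0   41.3   60.6
         expert    SD 106 150 70.7   62.9   77.4
             ai    SD  18  99 18.2   11.8   26.9
         gemini    SD   8  24 33.3   18.0   53.3
         claude    SD   2  25  8.0    2.2   25.0
 dermatologists SD_DD 256 375 68.3   63.4   72.8
             ai SD_DD  44  99 44.4   35.0   54.3
         gemini SD_DD  15  24 62.5   42.7   78.8
...
dermatologists_vs_ai [SD]: chi_square p = 1.53e-12
ai_models [SD_DD]: chi_square p = 0.0425
```

Reading: the 15 dermatologists were correct in 218 of 375 evaluations
(58.1%, Wilson 95% CI 53.1–63.0) on the primary diagnosis alone, the four AI
models in 18 of 99 (18.2%, 11.8–26.9) — a difference far beyond chance
(χ², p ≈ 10⁻¹²) — while the difference *between* the AI models is
significant only once differentials are counted (p = 0.042).

The same statistics on simulated data, end-to-end:

```python
from trichostudy import ResponseModel, StudyDesign, accuracy, gwet_ac1, simulate_responses

matrix = simulate_responses(StudyDesign(), ResponseModel(seed=1))
experts = accuracy(matrix, groups="expert")
print(f"experts: {experts.k}/{experts.n} = {100 * experts.proportion:.1f}%")
ai = gwet_ac1(matrix, raters=matrix.raters_in(["chatgpt", "grok", "gemini", "claude"]))
print(f"AI agreement: AC1 = {ai.ac1:.2f} ({ai.category})")
```

```
experts: 83/150 = 55.3%
AI agreement: AC1 = 0.62 (good)
```

(This seed happens to draw hard cases: the simulated experts land below
their 71% baseline because the shared case-difficulty offsets — sd 1.0 on
the log-odds scale — move all raters together.)

A full study run — synthetic images, transformation, integrity report,
simulated responses, accuracy/comparison/agreement tables, figure and a
manifest that reproduces every byte — is one call
(`trichostudy report --config study.yaml`, or `run_study` from Python).
Other subcommands (`simulate-images`, `transform`, `verify`, `score`,
`accuracy`, `agreement`) expose the individual stages.

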