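"""Published margins of the reference reader study.

The motivating head-to-head study (15 dermatologists in three experience
groups and four multimodal language models reading 25 trichoscopy cases,
with one model missing one evaluation) did not release its raw response
matrix, but its per-group accuracy table prints percentages from which the
underlying correct counts are recoverable exactly (e.g. 16.0% of 25
evaluations = 4; 33.3% of 24 = 8).  Those counts, the study roster, and the
reported headline agreement values live here so the analysis pipeline can
be exercised end-to-end on the study's own margins without any external
data.

Note: the experts' SD+DD count is derived from the pooled dermatologist
percentage (68.3% of 375 = 256, hence 256 - 71 - 65 = 120); the per-group
percentage printed for that single cell (80.3) is not attainable from 150
evaluations (120/150 = 80.0) and appears to be a rounding inconsistency in
the published table.
"""

from __future__ import annotations

from .synthetic import StudyDesign

#: the study roster and case grid: 5 residents, 4 board-certified
#: dermatologists, 6 trichology experts, 4 AI models, 25 cases, and a
#: single missing evaluation for one AI model (placed at the last case by
#: convention; the study never says which case it was).
REFERENCE_DESIGN = StudyDesign()

#: correct evaluations per group, suspected-diagnosis (SD) rule
SD_COUNTS = {
    "resident": 61,         # of 125 -> 48.8%
    "board_certified": 51,  # of 100 -> 51.0%
    "expert": 106,          # of 150 -> 70.7%
    "chatgpt": 4,           # of 25  -> 16.0%
    "grok": 4,              # of 25  -> 16.0%
    "gemini": 8,            # of 24  -> 33.3%
    "claude": 2,            # of 25  ->  8.0%
}

#: correct evaluations per group, SD + differential-diagnoses rule
SD_DD_COUNTS = {
    "resident": 71,         # of 125 -> 56.8%
    "board_certified": 65,  # of 100 -> 65.0%
    "expert": 120,          # of 150 -> 80.0% (derived; see module docstring)
    "chatgpt": 13,          # of 25  -> 52.0%
    "grok": 10,             # of 25  -> 40.0%
    "gemini": 15,           # of 24  -> 62.5%
    "claude": 6,            # of 25  -> 24.0%
}

#: descriptive roster of the 15 human readers
REFERENCE_ROSTER = {
    "training_status": {
        "resident": 5,
        "board_certified": 4,
        "expert": 6,
    },
    "experience_years": {
        "1-5": 5,
        "6-10": 3,
        "11-20": 2,
        "21+": 5,
    },
    "workplace": {
        "university_hospital": 7,
        "public_hospital": 3,
        "private_hospital": 1,
        "private_practice": 4,
    },
}
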