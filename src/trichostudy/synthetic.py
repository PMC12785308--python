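"""Synthetic study material: scalp-like images and simulated rater responses.

The real reader study compared 15 dermatologists (five residents, four
board-certified dermatologists, six trichology experts) and four multimodal
language models on ~25 trichoscopic images; its images and raw responses are
not public.  This module generates stand-ins with known ground truth:

* scalp-like images -- a skin-toned background with curvilinear hair-shaft
  strokes, filled follicular dots and optional colour patches, drawn with
  hard (non-anti-aliased) pixels so brute-force pixel oracles are exact;
* rater x case correctness matrices, either simulated from a logistic model
  (group baseline log-odds plus a per-case difficulty offset) or constructed
  deterministically to match prescribed correct-count margins.

Everything is a pure function of its inputs and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from skimage.draw import bezier_curve, disk

from ._util import subseed
from .scoring import CorrectnessMatrix

#: group labels of the human readers, in study order
DERMATOLOGIST_GROUPS = ("resident", "board_certified", "expert")
#: each AI model acts as a single-rater group
AI_GROUPS = ("chatgpt", "grok", "gemini", "claude")

PER_RATER = "per_rater"
PER_GROUP = "per_group"


@dataclass(frozen=True)
class ImageSpec:
    """Parameters of one synthetic trichoscopy-like image.

    Sizes are pixels, colours are 8-bit RGB triplets, darkness is how much
    darker than the background a structure is drawn.
    """

    height: int = 400
    width: int = 400
    background_color: tuple[int, int, int] = (228, 206, 188)
    n_hairs: int = 20
    hair_thickness_range: tuple[int, int] = (1, 3)
    hair_darkness_range: tuple[int, int] = (60, 140)
    n_follicular_dots: int = 12
    dot_radius_range: tuple[int, int] = (2, 4)
    patch_specs: tuple[tuple[tuple[int, int], int, tuple[int, int, int]], ...] = ()

    def __post_init__(self):
        if self.height < 64 or self.width < 64:
            raise ValueError("image dimensions must be at least 64 x 64")
        for name in ("n_hairs", "n_follicular_dots"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("hair_thickness_range", "hair_darkness_range", "dot_radius_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must satisfy min <= max")
        for c in self.background_color:
            if not 0 <= c <= 255:
                raise ValueError("background colour must lie in [0, 255]")


@dataclass(frozen=True)
class StudyDesign:
    """Rater roster and case grid of a reader study.

    ``groups`` lists (group label, rater count); single-rater groups (the AI
    models) use the group label itself as rater id, multi-rater groups use
    ``<group>_<i>``.  ``missing_cells`` marks (rater, case) pairs with no
    evaluation.
    """

    groups: tuple[tuple[str, int], ...] = (
        ("resident", 5),
        ("board_certified", 4),
        ("expert", 6),
        ("chatgpt", 1),
        ("grok", 1),
        ("gemini", 1),
        ("claude", 1),
    )
    n_cases: int = 25
    missing_cells: tuple[tuple[str, str], ...] = (("gemini", "case_25"),)

    def __post_init__(self):
        if self.n_cases <= 0:
            raise ValueError("n_cases must be positive")
        for name, count in self.groups:
            if count <= 0:
                raise ValueError(f"group {name!r} must have a positive rater count")
        raters = set(self.rater_ids())
        cases = set(self.case_ids())
        for rater, case in self.missing_cells:
            if rater not in raters:
                raise ValueError(f"missing cell refers to unknown rater {rater!r}")
            if case not in cases:
                raise ValueError(f"missing cell refers to unknown case {case!r}")

    def rater_ids(self) -> list[str]:
        out = []
        for name, count in self.groups:
            if count == 1:
                out.append(name)
            else:
                out.extend(f"{name}_{i + 1}" for i in range(count))
        return out

    def rater_groups(self) -> pd.Series:
        groups = {}
        for name, count in self.groups:
            if count == 1:
                groups[name] = name
            else:
                for i in range(count):
                    groups[f"{name}_{i + 1}"] = name
        return pd.Series(groups)

    def case_ids(self) -> list[str]:
        return [f"case_{i + 1}" for i in range(self.n_cases)]

    def present_mask(self) -> pd.DataFrame:
        """Boolean rater x case frame, False where the evaluation is missing."""
        mask = pd.DataFrame(True, index=self.rater_ids(), columns=self.case_ids())
        for rater, case in self.missing_cells:
            mask.loc[rater, case] = False
        return mask


@dataclass(frozen=True)
class ResponseModel:
    """Logistic correctness model: P(correct) = expit(group logit + case offset).

    Case offsets are drawn once per case from N(0, case_difficulty_sd), so
    all raters find the same cases hard -- the between-case heterogeneity
    that chance-corrected agreement statistics are sensitive to.
    """

    group_logits: Mapping[str, float] = field(
        default_factory=lambda: {
            "resident": -0.05,
            "board_certified": 0.04,
            "expert": 0.88,
            "chatgpt": -1.66,
            "grok": -1.66,
            "gemini": -0.69,
            "claude": -2.44,
        }
    )
    case_difficulty_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.case_difficulty_sd < 0:
            raise ValueError("case_difficulty_sd must be >= 0")


# ---------------------------------------------------------------------------
# image generation
# ---------------------------------------------------------------------------

def _clip_color(base: Sequence[int], delta: int) -> tuple[int, int, int]:
    return tuple(int(np.clip(c - delta, 0, 255)) for c in base)


def generate_scalp_image(spec: ImageSpec, seed: int):
    """Draw one synthetic scalp image; returns (RGB uint8 array, structures).

    Hair shafts are quadratic Bezier strokes thickened with a disk brush;
    follicular dots are filled circles; patches are drawn first so hairs
    overlay them.  ``structures`` lists every drawn element with its type
    and coordinates as ground truth.  Same (spec, seed) gives identical
    bytes.
    """
    rng = np.random.default_rng(seed)
    h, w = spec.height, spec.width
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = np.array(spec.background_color, dtype=np.uint8)
    structures: list[dict] = []

    for (cy, cx), radius, color in spec.patch_specs:
        rr, cc = disk((cy, cx), radius, shape=(h, w))
        img[rr, cc] = np.array(color, dtype=np.uint8)
        structures.append({"type": "patch", "center": (int(cy), int(cx)),
                           "radius": int(radius), "color": tuple(int(c) for c in color)})

    for _ in range(spec.n_follicular_dots):
        cy = int(rng.integers(0, h))
        cx = int(rng.integers(0, w))
        radius = int(rng.integers(spec.dot_radius_range[0], spec.dot_radius_range[1] + 1))
        darkness = int(rng.integers(spec.hair_darkness_range[0], spec.hair_darkness_range[1] + 1))
        rr, cc = disk((cy, cx), radius, shape=(h, w))
        img[rr, cc] = _clip_color(spec.background_color, darkness)
        structures.append({"type": "dot", "center": (cy, cx), "radius": radius,
                           "darkness": darkness})

    brush_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for _ in range(spec.n_hairs):
        p0 = rng.integers(0, (h, w))
        p2 = rng.integers(0, (h, w))
        mid = (p0 + p2) / 2.0
        bow = rng.normal(scale=0.15 * min(h, w), size=2)
        p1 = np.clip(mid + bow, 0, (h - 1, w - 1)).astype(int)
        thickness = int(rng.integers(spec.hair_thickness_range[0],
                                     spec.hair_thickness_range[1] + 1))
        darkness = int(rng.integers(spec.hair_darkness_range[0],
                                    spec.hair_darkness_range[1] + 1))
        rr, cc = bezier_curve(int(p0[0]), int(p0[1]), int(p1[0]), int(p1[1]),
                              int(p2[0]), int(p2[1]), weight=1.0, shape=(h, w))
        color = _clip_color(spec.background_color, darkness)
        radius = max(thickness // 2, 0)
        if radius == 0:
            img[rr, cc] = color
        else:
            if radius not in brush_cache:
                brush_cache[radius] = disk((0, 0), radius + 0.5)
            br, bc = brush_cache[radius]
            pr = (rr[:, None] + br[None, :]).ravel()
            pc = (cc[:, None] + bc[None, :]).ravel()
            keep = (pr >= 0) & (pr < h) & (pc >= 0) & (pc < w)
            img[pr[keep], pc[keep]] = color
        structures.append({
            "type": "hair",
            "control_points": [tuple(int(v) for v in p) for p in (p0, p1, p2)],
            "thickness": thickness,
            "darkness": darkness,
        })
    return img, structures


# ---------------------------------------------------------------------------
# response simulation
# ---------------------------------------------------------------------------

def simulate_responses(design: StudyDesign, model: ResponseModel) -> CorrectnessMatrix:
    """Simulate a correctness matrix under the logistic group/difficulty model.

    One Bernoulli draw per present (rater, case) cell with success
    probability expit(group logit + case offset); missing cells stay NaN.
    Reproducible from ``model.seed``.
    """
    groups = design.rater_groups()
    for g in groups.unique():
        if g not in model.group_logits:
            raise ValueError(f"no group logit supplied for group {g!r}")
    rng = np.random.default_rng(subseed(model.seed, "responses"))
    offsets = rng.normal(0.0, model.case_difficulty_sd, size=design.n_cases)
    mask = design.present_mask()
    values = pd.DataFrame(np.nan, index=mask.index, columns=mask.columns)
    for rater in mask.index:
        logit = float(model.group_logits[groups[rater]])
        p = expit(logit + offsets)
        draws = (rng.random(design.n_cases) < p).astype(float)
        present = mask.loc[rater].to_numpy()
        row = np.where(present, draws, np.nan)
        values.loc[rater] = row
    return CorrectnessMatrix(values, groups)


#: baseline log-odds that a wrong suspected diagnosis is rescued by one of
#: the differentials, per group (logit of the study's conditional upgrade
#: rates between the SD and SD+DD accuracy columns)
DEFAULT_UPGRADE_LOGITS = {
    "resident": -1.69,
    "board_certified": -0.92,
    "expert": -0.77,
    "chatgpt": -0.29,
    "grok": -0.92,
    "gemini": -0.25,
    "claude": -1.56,
}


def simulate_paired_matrices(
    design: StudyDesign,
    sd_model: ResponseModel,
    upgrade_logits: Mapping[str, float] | None = None,
) -> dict[str, CorrectnessMatrix]:
    """Simulate coupled SD and SD+DD correctness matrices.

    The SD matrix comes from ``sd_model``.  Each incorrect SD cell is then
    upgraded to correct with a probability governed by ``upgrade_logits``
    (same logistic structure, case offsets shared with the SD draw's
    difficulty), so the SD+DD matrix dominates the SD matrix cell-wise, as
    the scoring rule guarantees for real responses.
    """
    sd = simulate_responses(design, sd_model)
    upgrade_model = ResponseModel(
        group_logits=dict(upgrade_logits or DEFAULT_UPGRADE_LOGITS),
        case_difficulty_sd=sd_model.case_difficulty_sd,
        seed=subseed(sd_model.seed, "upgrade"),
    )
    upgrade = simulate_responses(design, upgrade_model)
    combined = sd.values.where(sd.values.isna(),
                               np.maximum(sd.values, upgrade.values))
    return {"SD": sd, "SD_DD": CorrectnessMatrix(combined, sd.groups)}


def matrix_from_margins(
    design: StudyDesign,
    correct_counts: Mapping[str, int],
    mode: str = PER_GROUP,
) -> CorrectnessMatrix:
    """Build a correctness matrix whose margins equal prescribed counts.

    ``correct_counts`` maps group labels (``per_group``) or rater ids
    (``per_rater``) to the number of correct cells.  Placement is
    deterministic: within each unit, present cells ordered by (case index,
    rater index) are set to 1 until the count is exhausted, so re-running
    always yields the same matrix.
    """
    if mode not in (PER_RATER, PER_GROUP):
        raise ValueError(f"mode must be {PER_RATER!r} or {PER_GROUP!r}")
    groups = design.rater_groups()
    mask = design.present_mask()
    cases = list(mask.columns)
    values = pd.DataFrame(np.nan, index=mask.index, columns=mask.columns)
    values[mask] = 0.0

    for unit, count in correct_counts.items():
        if mode == PER_RATER:
            if unit not in mask.index:
                raise ValueError(f"unknown rater id {unit!r}")
            raters = [unit]
        else:
            raters = [r for r in mask.index if groups[r] == unit]
            if not raters:
                raise ValueError(f"unknown group {unit!r}")
        cells = [(ci, r) for ci, c in enumerate(cases) for r in raters if mask.loc[r, c]]
        if count < 0 or count > len(cells):
            raise ValueError(
                f"count {count} for {unit!r} exceeds the {len(cells)} present cells"
            )
        for ci, r in cells[:count]:
            values.loc[r, cases[ci]] = 1.0
    return CorrectnessMatrix(values, groups)
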