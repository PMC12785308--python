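"""Study orchestration and publication-style table output.

``run_study`` drives the full pipeline from a single config: synthesize (or
load) images, transform them, verify integrity, obtain correctness
matrices, and emit the accuracy table (``table2.csv``), agreement table
(``table3.csv``), group comparisons, an integrity report, a bar chart and a
run manifest.  ``reference_margin_tables`` reproduces the accuracy
arithmetic of the reference study from its published margins alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import __version__
from ._util import subseed
from .agreement import AgreementResult, between_group_agreement, gwet_ac1
from .integrity import IntegrityThresholds, verify_directories
from .margins import REFERENCE_DESIGN, REFERENCE_ROSTER, SD_COUNTS, SD_DD_COUNTS
from .pipeline import TransformConfig, transform_batch
from .scoring import (SD, SD_DD, CorrectnessMatrix, build_matrix,
                      read_responses, read_truths)
from .stats import ComparisonResult, accuracy, compare_groups
from .synthetic import (AI_GROUPS, DERMATOLOGIST_GROUPS, ImageSpec,
                        ResponseModel, StudyDesign, generate_scalp_image,
                        matrix_from_margins, simulate_paired_matrices)

log = logging.getLogger(__name__)

MODES = (SD, SD_DD)


@dataclass
class StudyConfig:
    """Everything a full study run needs, driven by one master seed."""

    output_dir: Path = Path("study_output")
    master_seed: int = 0
    image_spec: ImageSpec = field(default_factory=ImageSpec)
    transform: TransformConfig = field(default_factory=TransformConfig)
    design: StudyDesign = field(default_factory=StudyDesign)
    sd_model: ResponseModel | None = None
    upgrade_logits: Mapping[str, float] | None = None
    thresholds: IntegrityThresholds = field(default_factory=IntegrityThresholds)
    ci_level: float = 0.95
    alpha: float = 0.05
    # optional real data; when set, scoring replaces simulation
    responses_path: Path | None = None
    truths_path: Path | None = None
    vocabulary_path: Path | None = None

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "output_dir" in raw:
            kwargs["output_dir"] = Path(raw["output_dir"])
        for key in ("master_seed", "ci_level", "alpha", "upgrade_logits"):
            if key in raw:
                kwargs[key] = raw[key]
        for key, typ in (("image_spec", ImageSpec), ("transform", TransformConfig),
                         ("design", StudyDesign), ("thresholds", IntegrityThresholds),
                         ("sd_model", ResponseModel)):
            if key in raw:
                section = dict(raw[key])
                for k, v in section.items():
                    if isinstance(v, list):
                        section[k] = tuple(tuple(x) if isinstance(x, list) else x
                                           for x in v) if any(isinstance(x, list) for x in v) else tuple(v)
                kwargs[key] = typ(**section)
        for key in ("responses_path", "truths_path", "vocabulary_path"):
            if key in raw and raw[key] is not None:
                p = Path(raw[key])
                if not p.exists():
                    raise FileNotFoundError(f"{key} does not exist: {p}")
                kwargs[key] = p
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def _pct(x: float) -> float:
    return round(100 * x, 1)


def accuracy_table(matrices: Mapping[str, CorrectnessMatrix],
                   level: float = 0.95) -> pd.DataFrame:
    """Per-group accuracy with Wilson CIs, pooled and per model.

    Long format, one row per (group, mode): group, mode, k, n, pct, ci_lo,
    ci_hi — the layout of the reference study's accuracy table.
    """
    rows = []
    for mode, m in matrices.items():
        selections = [("dermatologists", list(DERMATOLOGIST_GROUPS))]
        selections += [(g, [g]) for g in DERMATOLOGIST_GROUPS]
        selections += [("ai", list(AI_GROUPS))]
        selections += [(g, [g]) for g in AI_GROUPS]
        for label, groups in selections:
            res = accuracy(m, groups=groups, label=label, mode=mode, level=level)
            rows.append({
                "group": res.label, "mode": mode, "k": res.k, "n": res.n,
                "pct": _pct(res.proportion),
                "ci_lo": _pct(res.ci_lower), "ci_hi": _pct(res.ci_upper),
            })
    return pd.DataFrame(rows)


def comparison_results(matrices: Mapping[str, CorrectnessMatrix],
                       alpha: float = 0.05, seed: int = 0
                       ) -> dict[tuple[str, str], ComparisonResult]:
    """The study's three group contrasts, per scoring mode."""
    derm_pool = {g: "dermatologists" for g in DERMATOLOGIST_GROUPS}
    derm_pool.update({g: "ai" for g in AI_GROUPS})
    out: dict[tuple[str, str], ComparisonResult] = {}
    for mode, m in matrices.items():
        out[("dermatologists_vs_ai", mode)] = compare_groups(
            m, groups=list(DERMATOLOGIST_GROUPS) + list(AI_GROUPS),
            grouping=derm_pool, alpha=alpha, seed=subseed(seed, mode, "dva"))
        out[("dermatologist_groups", mode)] = compare_groups(
            m, groups=list(DERMATOLOGIST_GROUPS), alpha=alpha,
            seed=subseed(seed, mode, "derm"))
        out[("ai_models", mode)] = compare_groups(
            m, groups=list(AI_GROUPS), alpha=alpha,
            seed=subseed(seed, mode, "ai"))
    return out


def comparisons_table(results: Mapping[tuple[str, str], ComparisonResult]
                      ) -> pd.DataFrame:
    rows = []
    for (name, mode), res in results.items():
        rows.append({"comparison": name, "mode": mode, "kind": "omnibus",
                     "test": res.test, "statistic": res.statistic,
                     "df": res.df, "p_raw": res.p_value, "p_adjusted": np.nan})
        for pw in res.pairwise:
            rows.append({"comparison": f"{name}:{pw.group_a}_vs_{pw.group_b}",
                         "mode": mode, "kind": "pairwise", "test": pw.test,
                         "statistic": np.nan, "df": np.nan,
                         "p_raw": pw.p_raw, "p_adjusted": pw.p_adjusted})
    return pd.DataFrame(rows)


def agreement_table(matrices: Mapping[str, CorrectnessMatrix],
                    level: float = 0.95) -> pd.DataFrame:
    """AC1 per rater group plus the two between-group constructions.

    Mirrors the reference study's reliability table: one row per (group,
    mode) with AC1, CI, interpretation band, and the sizes involved.
    'between_groups' collapses each dermatologist group to its majority
    vote; 'dermatologists_vs_ai' opposes the pooled majority votes.
    """
    rows = []
    for mode, m in matrices.items():
        results: list[AgreementResult] = [
            gwet_ac1(m, raters=m.raters_in(list(DERMATOLOGIST_GROUPS)),
                     label="dermatologists", level=level)]
        for g in DERMATOLOGIST_GROUPS:
            results.append(gwet_ac1(m, raters=m.raters_in(g), label=g, level=level))
        results.append(between_group_agreement(
            m, grouping={g: [g] for g in DERMATOLOGIST_GROUPS},
            label="between_groups", level=level))
        results.append(gwet_ac1(m, raters=m.raters_in(list(AI_GROUPS)),
                                label="ai", level=level))
        results.append(between_group_agreement(
            m, grouping={"dermatologists": list(DERMATOLOGIST_GROUPS),
                         "ai": list(AI_GROUPS)},
            label="dermatologists_vs_ai", level=level))
        for r in results:
            rows.append({"group": r.label, "mode": mode,
                         "ac1": round(r.ac1, 4), "ci_lo": round(r.ci_lower, 4),
                         "ci_hi": round(r.ci_upper, 4), "category": r.category,
                         "n_items": r.n_items, "n_raters": r.n_raters})
    return pd.DataFrame(rows)


def describe_raters(roster: pd.DataFrame) -> pd.DataFrame:
    """Frequency table (n, %) of each categorical roster column.

    Percentages are rounded to one decimal and may not sum to exactly 100.
    """
    rows = []
    n = len(roster)
    for col in roster.columns:
        counts = roster[col].value_counts(sort=False)
        for level_name, count in counts.items():
            rows.append({"variable": col, "level": level_name,
                         "n": int(count), "pct": round(100 * count / n, 1)})
    return pd.DataFrame(rows, columns=["variable", "level", "n", "pct"])


def roster_frame(roster: Mapping[str, Mapping[str, int]] = REFERENCE_ROSTER
                 ) -> pd.DataFrame:
    """Expand {variable: {level: count}} into one row per rater."""
    cols = {}
    for var, levels in roster.items():
        vals = []
        for level_name, count in levels.items():
            vals.extend([level_name] * count)
        cols[var] = vals
    return pd.DataFrame(cols)


def accuracy_figure(table2: pd.DataFrame, path) -> None:
    """Grouped bar chart of per-group accuracy, one bar pair per group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = table2[table2["mode"] == SD]["group"].tolist()
    x = np.arange(len(groups))
    fig, ax = plt.subplots(figsize=(8, 4))
    for offset, mode in zip((-0.2, 0.2), MODES):
        sub = table2[table2["mode"] == mode].set_index("group").loc[groups]
        ax.bar(x + offset, sub["pct"], width=0.4, label=mode.replace("_", "+"))
    ax.set_xticks(x, groups, rotation=30, ha="right")
    ax.set_ylabel("accuracy (%)")
    ax.set_ylim(0, 100)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# reference-margins reproduction
# ---------------------------------------------------------------------------

def reference_margin_matrices() -> dict[str, CorrectnessMatrix]:
    """Correctness matrices whose margins equal the published study counts."""
    return {
        SD: matrix_from_margins(REFERENCE_DESIGN, SD_COUNTS),
        SD_DD: matrix_from_margins(REFERENCE_DESIGN, SD_DD_COUNTS),
    }


def reference_margin_tables(output_dir=None, seed: int = 0):
    """Accuracy table and group comparisons from the published margins.

    Only margin-determined quantities are meaningful here: percentages,
    Wilson CIs and the contingency tests depend on the counts alone.
    Agreement statistics are *not* computed — they depend on the joint
    rater-by-case pattern, which the margins do not determine.
    """
    matrices = reference_margin_matrices()
    table2 = accuracy_table(matrices)
    comps = comparison_results(matrices, seed=seed)
    table1 = describe_raters(roster_frame())
    if output_dir is not None:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        table1.to_csv(output_dir / "table1.csv", index=False)
        table2.to_csv(output_dir / "table2.csv", index=False)
        comparisons_table(comps).to_csv(output_dir / "comparisons.csv", index=False)
    return table2, comps, table1


# ---------------------------------------------------------------------------
# full study run
# ---------------------------------------------------------------------------

def _setup_logging(out_dir: Path) -> None:
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s: %(message)s"))
    logging.getLogger("trichostudy").addHandler(handler)
    logging.getLogger("trichostudy").setLevel(logging.INFO)


def run_study(config: StudyConfig) -> dict:
    """Run transform -> verify -> score -> accuracy -> comparisons -> agreement.

    Returns a bundle of DataFrames/results; all outputs are also written
    under ``config.output_dir`` together with a manifest that fully
    determines every byte (config, seeds, package version).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    manifest: dict = {
        "version": __version__,
        "master_seed": config.master_seed,
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "completed_stages": [],
    }

    def checkpoint(stage: str) -> None:
        manifest["completed_stages"].append(stage)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    try:
        # 1. synthetic originals, one per case
        orig_dir = out / "images_original"
        orig_dir.mkdir(exist_ok=True)
        for case in config.design.case_ids():
            img, _ = generate_scalp_image(config.image_spec,
                                          subseed(config.master_seed, "image", case))
            Image.fromarray(img).save(orig_dir / f"{case}.png")
        log.info("generated %d synthetic images", config.design.n_cases)
        checkpoint("simulate_images")

        # 2. anti-leakage transform
        trans_dir = out / "images_transformed"
        records = transform_batch(orig_dir, trans_dir, config.transform,
                                  subseed(config.master_seed, "transform"))
        checkpoint("transform")

        # 3. integrity verification
        reports = verify_directories(orig_dir, trans_dir, out / "integrity.csv",
                                     config.thresholds)
        n_fail = sum(not r.passed for r in reports)
        if n_fail:
            log.warning("%d/%d image pairs failed integrity thresholds",
                        n_fail, len(reports))
        checkpoint("verify")

        # 4. correctness matrices: scored from real responses, or simulated
        if config.responses_path is not None:
            if config.truths_path is None:
                raise FileNotFoundError("truths_path is required with responses_path")
            vocab = None
            if config.vocabulary_path is not None:
                vocab = yaml.safe_load(Path(config.vocabulary_path).read_text())
            responses = read_responses(config.responses_path, vocab)
            truths = read_truths(config.truths_path, vocab)
            matrices = {mode: build_matrix(responses, truths, mode)
                        for mode in MODES}
        else:
            sd_model = config.sd_model or ResponseModel(
                seed=subseed(config.master_seed, "responses"))
            matrices = simulate_paired_matrices(config.design, sd_model,
                                                config.upgrade_logits)
        for mode, m in matrices.items():
            m.to_csv(out / f"matrix_{mode.lower()}.csv")
        checkpoint("score")

        # 5-7. accuracy, comparisons, agreement
        table2 = accuracy_table(matrices, level=config.ci_level)
        table2.to_csv(out / "table2.csv", index=False)
        checkpoint("accuracy")

        comps = comparison_results(matrices, alpha=config.alpha,
                                   seed=config.master_seed)
        comparisons_table(comps).to_csv(out / "comparisons.csv", index=False)
        checkpoint("comparisons")

        table3 = agreement_table(matrices, level=config.ci_level)
        table3.to_csv(out / "table3.csv", index=False)
        checkpoint("agreement")

        accuracy_figure(table2, out / "accuracy.png")
        checkpoint("figure")
    except Exception as exc:
        manifest["failed"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    return {"table2": table2, "table3": table3, "comparisons": comps,
            "integrity": reports, "records": records, "matrices": matrices,
            "manifest": manifest}
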