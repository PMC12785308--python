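"""Turn diagnosis responses into binary correctness data.

A reader study collects, per rater and case, a suspected diagnosis (SD) and
up to three differential diagnoses (DD).  A response is *correct* under the
SD rule iff the suspected diagnosis equals the verified true diagnosis, and
under the SD+DD rule iff the truth appears among the suspected diagnosis or
any differential.  The resulting rater x case grid of 0/1 cells (with
missing entries allowed) is the input to every statistic in this package.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: scoring modes
SD = "SD"
SD_DD = "SD_DD"

_NORMALIZE_RE = re.compile(r"[\s\-_/\\,.;:()'\"!?]+")


def canonicalize_label(raw: str | None, vocabulary: Mapping[str, str] | None = None) -> str | None:
    """Normalize a free-text diagnosis label and apply a synonym map.

    Lowercases, collapses runs of whitespace and punctuation to single
    spaces, trims, then looks the result up in ``vocabulary`` (whose keys
    are expected in the same normalized form).  Unmapped labels pass through
    normalized.  Empty input returns ``None`` (the missing marker).
    """
    if raw is None:
        return None
    s = _NORMALIZE_RE.sub(" ", str(raw).lower()).strip()
    if not s:
        return None
    if vocabulary:
        s = vocabulary.get(s, s)
    return s


def canonicalize_vocabulary(vocabulary: Mapping[str, str]) -> dict[str, str]:
    """Normalize the keys of a synonym map so lookups match canonical forms."""
    out: dict[str, str] = {}
    for k, v in vocabulary.items():
        key = canonicalize_label(k)
        if key is not None:
            out[key] = v
    return out


@dataclass(frozen=True)
class ResponseRecord:
    """One rater's answer for one case (labels already canonicalized)."""

    rater_id: str
    group: str
    case_id: str
    suspected: str | None
    differentials: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.differentials) > 3:
            raise ValueError(
                f"at most 3 differential diagnoses allowed, got {len(self.differentials)}"
            )


def score_response(resp: ResponseRecord, truth: str, mode: str = SD) -> int:
    """Score one response against the true diagnosis: 1 correct, 0 incorrect.

    ``SD`` counts only the suspected diagnosis; ``SD_DD`` also accepts the
    truth anywhere among the differentials.  A missing suspected diagnosis
    scores 0 (a warning is logged).
    """
    if mode not in (SD, SD_DD):
        raise ValueError(f"unknown scoring mode: {mode!r}")
    if resp.suspected is None:
        log.warning("missing suspected diagnosis for rater %s case %s; scored 0",
                    resp.rater_id, resp.case_id)
        return 0
    if resp.suspected == truth:
        return 1
    if mode == SD_DD and truth in resp.differentials:
        return 1
    return 0


@dataclass
class CorrectnessMatrix:
    """Rater x case grid of binary correctness with missing entries.

    ``values`` is a DataFrame indexed by rater id with case-id columns;
    cells are 0.0, 1.0 or NaN (missing).  ``groups`` maps each rater id to
    its group label.
    """

    values: pd.DataFrame
    groups: pd.Series
    flags: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        self.groups = self.groups.reindex(self.values.index)
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValueError(f"raters without a group label: {missing}")
        cells = self.values.to_numpy(dtype=float)
        ok = np.isnan(cells) | (cells == 0) | (cells == 1)
        if not ok.all():
            raise ValueError("matrix cells must be 0, 1 or missing")

    # -- selection ---------------------------------------------------------
    @property
    def rater_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def case_ids(self) -> list[str]:
        return list(self.values.columns)

    def raters_in(self, groups: str | Sequence[str]) -> list[str]:
        if isinstance(groups, str):
            groups = [groups]
        wanted = set(groups)
        unknown = wanted - set(self.groups.unique())
        if unknown:
            raise KeyError(f"unknown group(s): {sorted(unknown)}")
        return [r for r in self.values.index if self.groups[r] in wanted]

    def subset(self, raters: Iterable[str]) -> "CorrectnessMatrix":
        raters = list(raters)
        return CorrectnessMatrix(self.values.loc[raters].copy(), self.groups.loc[raters].copy())

    def counts(self, raters: Iterable[str] | None = None) -> tuple[int, int]:
        """(correct, evaluated) over the selected raters (default: all)."""
        sub = self.values if raters is None else self.values.loc[list(raters)]
        arr = sub.to_numpy(dtype=float)
        n = int(np.isfinite(arr).sum())
        k = int(np.nansum(arr))
        return k, n

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        """Wide CSV: rater_id, group, then one column per case (missing blank)."""
        out = self.values.copy()
        out.insert(0, "group", self.groups)
        out.index.name = "rater_id"
        out.to_csv(path, na_rep="")

    @classmethod
    def from_csv(cls, path) -> "CorrectnessMatrix":
        df = pd.read_csv(path, index_col="rater_id", dtype={"rater_id": str})
        groups = df.pop("group").astype(str)
        return cls(df.astype(float), groups)


def build_matrix(
    responses: Sequence[ResponseRecord],
    truths: Mapping[str, str],
    mode: str = SD,
) -> CorrectnessMatrix:
    """Score a response set into a CorrectnessMatrix.

    Every response's case must have an entry in ``truths`` (unknown cases
    raise, listing the offenders).  (rater, case) pairs with no response
    become missing cells.  Responses with a missing suspected diagnosis are
    scored 0 and recorded in ``matrix.flags``.
    """
    unknown = sorted({r.case_id for r in responses if r.case_id not in truths})
    if unknown:
        raise ValueError(f"responses reference cases with no ground truth: {unknown}")
    seen: set[tuple[str, str]] = set()
    raters: list[str] = []
    groups: dict[str, str] = {}
    cases: list[str] = []
    cells: dict[tuple[str, str], int] = {}
    flags: list[tuple[str, str]] = []
    for r in responses:
        key = (r.rater_id, r.case_id)
        if key in seen:
            raise ValueError(f"duplicate response for rater {r.rater_id} case {r.case_id}")
        seen.add(key)
        if r.rater_id not in groups:
            raters.append(r.rater_id)
            groups[r.rater_id] = r.group
        elif groups[r.rater_id] != r.group:
            raise ValueError(f"rater {r.rater_id} appears with two group labels")
        if r.case_id not in cells or r.case_id not in set(cases):
            if r.case_id not in cases:
                cases.append(r.case_id)
        if r.suspected is None:
            flags.append(key)
        cells[key] = score_response(r, truths[r.case_id], mode)
    values = pd.DataFrame(np.nan, index=pd.Index(raters, name="rater_id"), columns=cases)
    for (rater, case), v in cells.items():
        values.loc[rater, case] = float(v)
    return CorrectnessMatrix(values, pd.Series(groups), flags=flags)


def read_responses(path, vocabulary: Mapping[str, str] | None = None) -> list[ResponseRecord]:
    """Read a long-form responses CSV (rater_id, group, case_id, sd, dd1..dd3)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"rater_id", "group", "case_id", "sd"}
    if not required.issubset(df.columns):
        raise ValueError(f"responses CSV must have columns {sorted(required)}")
    vocab = canonicalize_vocabulary(vocabulary) if vocabulary else None
    out = []
    for row in df.itertuples(index=False):
        dds = []
        for col in ("dd1", "dd2", "dd3"):
            v = canonicalize_label(getattr(row, col, ""), vocab)
            if v is not None:
                dds.append(v)
        out.append(
            ResponseRecord(
                rater_id=str(row.rater_id),
                group=str(row.group),
                case_id=str(row.case_id),
                suspected=canonicalize_label(row.sd, vocab),
                differentials=tuple(dds),
            )
        )
    return out


def read_truths(path, vocabulary: Mapping[str, str] | None = None) -> dict[str, str]:
    """Read the ground-truth CSV (case_id, diagnosis) into a mapping."""
    df = pd.read_csv(path, dtype=str)
    if not {"case_id", "diagnosis"}.issubset(df.columns):
        raise ValueError("truths CSV must have columns case_id, diagnosis")
    vocab = canonicalize_vocabulary(vocabulary) if vocabulary else None
    truths = {}
    for row in df.itertuples(index=False):
        label = canonicalize_label(row.diagnosis, vocab)
        if label is None:
            raise ValueError(f"case {row.case_id} has an empty true diagnosis")
        truths[str(row.case_id)] = label
    return truths
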