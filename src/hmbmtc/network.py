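"""Evidence network of randomized trials comparing heavy-menstrual-bleeding treatments.

The unit of evidence is an arm-level observation: one treatment arm of one
randomized study, measured at one follow-up time, reporting the menstrual
blood loss (MBL) outcome in one of four forms (counts below threshold,
mean+SD, median+range, median+quartiles) on either the objective MBL scale
(mL, alkaline hematin method) or the pictorial PBAC score (Higham chart).

Nodes of the network are the eight treatment classes; an edge at follow-up
time ``t`` is a direct within-study comparison: two distinct classes in the
same study, each with an outcome recorded at that same ``t``.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "TreatmentClass",
    "OutcomeForm",
    "Scale",
    "ArmOutcome",
    "ComparisonSummary",
    "EvidenceNetwork",
    "NetworkValidationError",
    "load_network",
    "direct_comparison_table",
    "classes_at_time",
    "connected_components_at_time",
]


class TreatmentClass(str, enum.Enum):
    """The eight treatment classes for heavy menstrual bleeding."""

    COC = "COC"                  # combined oral contraceptives
    DANAZOL = "DANAZOL"
    ABLATION = "ABLATION"        # endometrial ablation / resection (all generations)
    LNG_IUS = "LNG_IUS"          # levonorgestrel-releasing intrauterine system
    PLACEBO = "PLACEBO"
    PROG_LT2WK = "PROG_LT2WK"    # progestogens < 2 weeks out of 4 (luteal phase)
    PROG_3WK = "PROG_3WK"        # progestogens ~ 3 weeks out of 4
    TXA = "TXA"                  # tranexamic acid

    def __str__(self) -> str:  # canonical label on output
        return self.value


# case-insensitive input aliases -> canonical class
_CLASS_ALIASES: dict[str, TreatmentClass] = {}
for _tc in TreatmentClass:
    _CLASS_ALIASES[_tc.value.lower()] = _tc
_CLASS_ALIASES.update(
    {
        "lng-ius": TreatmentClass.LNG_IUS,
        "lngius": TreatmentClass.LNG_IUS,
        "ius": TreatmentClass.LNG_IUS,
        "cocs": TreatmentClass.COC,
        "prog<2wks": TreatmentClass.PROG_LT2WK,
        "prog_lt2wks": TreatmentClass.PROG_LT2WK,
        "prog~3wks": TreatmentClass.PROG_3WK,
        "prog_3wks": TreatmentClass.PROG_3WK,
        "tranexamic_acid": TreatmentClass.TXA,
    }
)


def parse_treatment_class(label: str | TreatmentClass) -> TreatmentClass:
    """Resolve a (case-insensitive) label to its canonical treatment class."""
    if isinstance(label, TreatmentClass):
        return label
    key = str(label).strip().lower()
    try:
        return _CLASS_ALIASES[key]
    except KeyError:
        raise ValueError(
            f"unknown treatment class {label!r}; expected one of "
            f"{[t.value for t in TreatmentClass]}"
        ) from None


class OutcomeForm(str, enum.Enum):
    COUNTS = "COUNTS"
    MEAN_SD = "MEAN_SD"
    MEDIAN_RANGE = "MEDIAN_RANGE"
    MEDIAN_IQR = "MEDIAN_IQR"


class Scale(str, enum.Enum):
    MBL = "MBL"    # menstrual blood loss in mL; efficacy threshold 80 mL
    PBAC = "PBAC"  # pictorial chart score; threshold 100 treated as MBL < 80 mL


class NetworkValidationError(ValueError):
    """Raised when input rows violate arm-outcome invariants; row-addressed."""

    def __init__(self, messages: Sequence[str]):
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


@dataclass(frozen=True)
class ArmOutcome:
    """One arm of one study observed at one follow-up time.

    Exactly the fields required by ``form`` must be present: ``y`` for
    COUNTS; ``mean``/``sd`` for MEAN_SD; ``median``/``min_``/``max_`` for
    MEDIAN_RANGE; ``median``/``q1``/``q3`` for MEDIAN_IQR.  ``n`` is the arm
    size at that time in every form.  ``baseline_mean`` (mL) is the arm's
    mean baseline MBL, optional — in the source literature only 15 of 34
    studies reported it.
    """

    study_id: str
    treatment: TreatmentClass
    time_months: int
    form: OutcomeForm
    n: int
    scale: Scale = Scale.MBL
    y: int | None = None
    mean: float | None = None
    sd: float | None = None
    median: float | None = None
    min_: float | None = None
    max_: float | None = None
    q1: float | None = None
    q3: float | None = None
    baseline_mean: float | None = None
    arm_label: str = ""  # distinguishes two same-class arms within a study

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty if valid)."""
        errs: list[str] = []
        if self.time_months is None or self.time_months <= 0:
            errs.append(f"time_months must be a positive integer, got {self.time_months}")
        if self.n is None or self.n < 1:
            errs.append(f"n must be >= 1, got {self.n}")
        f = self.form
        if f is OutcomeForm.COUNTS:
            if self.y is None or self.y < 0 or (self.n is not None and self.y > self.n):
                errs.append(f"COUNTS requires 0 <= y <= n, got y={self.y}, n={self.n}")
        elif f is OutcomeForm.MEAN_SD:
            if self.mean is None or self.sd is None or self.sd <= 0:
                errs.append(f"MEAN_SD requires mean and sd > 0, got mean={self.mean}, sd={self.sd}")
        elif f is OutcomeForm.MEDIAN_RANGE:
            ok = (
                self.median is not None
                and self.min_ is not None
                and self.max_ is not None
                and self.min_ <= self.median <= self.max_
            )
            if not ok:
                errs.append(
                    f"MEDIAN_RANGE requires min <= median <= max, got "
                    f"min={self.min_}, median={self.median}, max={self.max_}"
                )
        elif f is OutcomeForm.MEDIAN_IQR:
            ok = (
                self.median is not None
                and self.q1 is not None
                and self.q3 is not None
                and self.q1 <= self.median <= self.q3
            )
            if not ok:
                errs.append(
                    f"MEDIAN_IQR requires q1 <= median <= q3, got "
                    f"q1={self.q1}, median={self.median}, q3={self.q3}"
                )
        if self.baseline_mean is not None and self.baseline_mean <= 0:
            errs.append(f"baseline_mean must be > 0 when present, got {self.baseline_mean}")
        return errs

    @property
    def key(self) -> tuple:
        """Duplicate-detection key: (study, class, arm label, time, scale)."""
        return (self.study_id, self.treatment, self.arm_label, self.time_months, self.scale)


def _pair(a: TreatmentClass, b: TreatmentClass) -> tuple[TreatmentClass, TreatmentClass]:
    """Canonical (lexicographic) ordering of an unordered class pair."""
    return (a, b) if a.value <= b.value else (b, a)


@dataclass(frozen=True)
class ComparisonSummary:
    """One Table-1-style row: a class pair and its direct-comparison profile."""

    pair: tuple[TreatmentClass, TreatmentClass]
    n_rcts: int
    total_patients: int
    counts_by_time: Mapping[int, int]


@dataclass
class EvidenceNetwork:
    """Collection of arm-level observations plus derived graph structure."""

    arms: list[ArmOutcome] = field(default_factory=list)

    # -- basic structure ---------------------------------------------------
    @property
    def studies(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.arms:
            seen.setdefault(a.study_id)
        return list(seen)

    @property
    def nodes(self) -> set[TreatmentClass]:
        return {a.treatment for a in self.arms}

    @property
    def times(self) -> list[int]:
        return sorted({a.time_months for a in self.arms})

    def __len__(self) -> int:
        return len(self.arms)

    def arms_of(self, study_id: str) -> list[ArmOutcome]:
        return [a for a in self.arms if a.study_id == study_id]

    def edges(self, t: int) -> list[tuple[str, tuple[TreatmentClass, TreatmentClass]]]:
        """Direct comparisons at time ``t`` as (study, canonical pair) records.

        One record per comparing study per pair: both classes must report an
        outcome at the same ``t`` within that study.
        """
        out = []
        by_study: dict[str, set[TreatmentClass]] = {}
        for a in self.arms:
            if a.time_months == t:
                by_study.setdefault(a.study_id, set()).add(a.treatment)
        for sid in sorted(by_study):
            classes = sorted(by_study[sid], key=lambda c: c.value)
            for i in range(len(classes)):
                for j in range(i + 1, len(classes)):
                    out.append((sid, _pair(classes[i], classes[j])))
        return out

    # -- I/O ---------------------------------------------------------------
    _COLUMNS = [
        "study_id", "class", "time_months", "scale", "form", "y", "n",
        "mean", "sd", "median", "min", "max", "q1", "q3", "baseline_mean",
    ]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EvidenceNetwork":
        missing = [c for c in ("study_id", "class", "time_months", "form", "n") if c not in df.columns]
        if missing:
            raise NetworkValidationError([f"missing required columns: {missing}"])

        def _num(row, col, integer=False):
            if col not in df.columns:
                return None
            v = row[col]
            if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
                return None
            try:
                return int(v) if integer else float(v)
            except (TypeError, ValueError):
                raise ValueError(f"malformed numeric field {col!r}: {v!r}")

        arms: list[ArmOutcome] = []
        errors: list[str] = []
        seen_keys: set[tuple] = set()
        for idx, row in df.iterrows():
            where = f"row {idx}"
            try:
                tc = parse_treatment_class(row["class"])
                scale = Scale(str(row.get("scale", "MBL") or "MBL").upper())
                form = OutcomeForm(str(row["form"]).upper())
                arm = ArmOutcome(
                    study_id=str(row["study_id"]),
                    treatment=tc,
                    time_months=_num(row, "time_months", integer=True),
                    form=form,
                    n=_num(row, "n", integer=True),
                    scale=scale,
                    y=_num(row, "y", integer=True),
                    mean=_num(row, "mean"),
                    sd=_num(row, "sd"),
                    median=_num(row, "median"),
                    min_=_num(row, "min"),
                    max_=_num(row, "max"),
                    q1=_num(row, "q1"),
                    q3=_num(row, "q3"),
                    baseline_mean=_num(row, "baseline_mean"),
                    arm_label=str(row["arm_label"]) if "arm_label" in df.columns and not pd.isna(row.get("arm_label")) else "",
                )
            except (ValueError, KeyError) as e:
                errors.append(f"{where}: {e}")
                continue
            violations = arm.validate()
            if violations:
                errors.extend(f"{where}: {v}" for v in violations)
                continue
            if arm.key in seen_keys:
                errors.append(f"{where}: duplicate record for {arm.key}")
                continue
            seen_keys.add(arm.key)
            arms.append(arm)
        if errors:
            raise NetworkValidationError(errors)
        return cls(arms)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.arms:
            rows.append(
                {
                    "study_id": a.study_id,
                    "arm_label": a.arm_label,
                    "class": a.treatment.value,
                    "time_months": a.time_months,
                    "scale": a.scale.value,
                    "form": a.form.value,
                    "y": a.y,
                    "n": a.n,
                    "mean": a.mean,
                    "sd": a.sd,
                    "median": a.median,
                    "min": a.min_,
                    "max": a.max_,
                    "q1": a.q1,
                    "q3": a.q3,
                    "baseline_mean": a.baseline_mean,
                }
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_csv(cls, path) -> "EvidenceNetwork":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def from_json(cls, path) -> "EvidenceNetwork":
        with open(path) as fh:
            records = json.load(fh)
        return cls.from_frame(pd.DataFrame.from_records(records))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def structure_json(self) -> dict:
        """Nodes and per-time edge lists, JSON-serializable."""
        return {
            "nodes": sorted(c.value for c in self.nodes),
            "edges_by_time": {
                str(t): sorted({f"{p[0]}|{p[1]}" for _, p in self.edges(t)})
                for t in self.times
            },
        }


def load_network(path, schema_options: Mapping | None = None) -> EvidenceNetwork:
    """Load and validate an evidence network from CSV or JSON.

    Rows violating arm-outcome invariants, unknown class labels, duplicate
    (study, class-arm, time, scale) records and malformed numerics are all
    rejected with row-addressed messages collected into a single
    :class:`NetworkValidationError`.
    """
    fmt = (schema_options or {}).get("format")
    p = str(path)
    if fmt == "json" or (fmt is None and p.endswith(".json")):
        return EvidenceNetwork.from_json(path)
    return EvidenceNetwork.from_csv(path)


def direct_comparison_table(net: EvidenceNetwork) -> list[ComparisonSummary]:
    """Summarize direct comparisons per class pair, mirroring the source table.

    A pair appears whenever >= 1 study contains arms of both classes at any
    times (its ``n_rcts``); the per-time counts require a *common* follow-up
    time, so a study whose two arms report at disjoint times contributes a
    comparing RCT but zero per-time comparisons.  ``total_patients`` sums,
    over comparing studies, each comparing arm's maximum reported n across
    times (the literature reports totals "usually at baseline").
    """
    pair_studies: dict[tuple, set[str]] = {}
    by_study: dict[str, list[ArmOutcome]] = {}
    for a in net.arms:
        by_study.setdefault(a.study_id, []).append(a)
    for sid, arms in by_study.items():
        classes = sorted({a.treatment for a in arms}, key=lambda c: c.value)
        for i in range(len(classes)):
            for j in range(i + 1, len(classes)):
                pair_studies.setdefault(_pair(classes[i], classes[j]), set()).add(sid)

    times = net.times
    edge_counts: dict[int, dict[tuple, int]] = {t: {} for t in times}
    for t in times:
        for _, pair in net.edges(t):
            edge_counts[t][pair] = edge_counts[t].get(pair, 0) + 1

    out: list[ComparisonSummary] = []
    for pair in sorted(pair_studies, key=lambda p: (p[0].value, p[1].value)):
        sids = pair_studies[pair]
        total = 0
        for sid in sids:
            # per comparing arm, the largest n reported at any time
            arm_max: dict[tuple, int] = {}
            for a in by_study[sid]:
                if a.treatment in pair:
                    k = (a.treatment, a.arm_label)
                    arm_max[k] = max(arm_max.get(k, 0), a.n)
            total += sum(arm_max.values())
        counts = {t: edge_counts[t].get(pair, 0) for t in times if edge_counts[t].get(pair, 0) > 0}
        out.append(
            ComparisonSummary(
                pair=pair, n_rcts=len(sids), total_patients=total, counts_by_time=counts
            )
        )
    return out


def comparison_table_frame(table: list[ComparisonSummary]) -> pd.DataFrame:
    """Render comparison summaries as a tidy frame (one column per time)."""
    times = sorted({t for row in table for t in row.counts_by_time})
    recs = []
    for row in table:
        rec = {
            "comparison": f"{row.pair[0]} & {row.pair[1]}",
            "n_rcts": row.n_rcts,
            "total_n": row.total_patients,
        }
        for t in times:
            rec[f"m{t}"] = row.counts_by_time.get(t, 0)
        recs.append(rec)
    return pd.DataFrame(recs)


def classes_at_time(net: EvidenceNetwork, t: int) -> set[TreatmentClass]:
    """Treatment classes involved in >= 1 direct comparison at time ``t``."""
    if t <= 0:
        raise ValueError("follow-up time must be positive")
    out: set[TreatmentClass] = set()
    for _, (a, b) in net.edges(t):
        out.add(a)
        out.add(b)
    return out


def connected_components_at_time(net: EvidenceNetwork, t: int) -> list[set[TreatmentClass]]:
    """Partition of ``classes_at_time(t)`` into connected components."""
    if t <= 0:
        raise ValueError("follow-up time must be positive")
    g = nx.Graph()
    for _, (a, b) in net.edges(t):
        g.add_edge(a, b)
    comps = [set(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda s: sorted(c.value for c in s))
    return comps
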