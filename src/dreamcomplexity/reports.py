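"""Serial-awakening dream-report categories and experience classification.

Upon each awakening two questions are asked: Q1 "What did you
experience?" (answer categorized by the level of detail: nothing,
no_info, white, vague, vivid) and Q2 "Did you experience anything?"
(no, no_info, maybe, yes).  The two answers are combined into a single
three-way experience classification:

* ``experience`` — the combined evidence suggests an experience,
* ``no_experience`` — the evidence positively suggests none,
* ``no_information`` — the awakening is uninformative.

The default rule applies, in order:

1. Q1 in {white, vague, vivid}           -> experience
2. else Q2 == yes                        -> experience
3. else Q1 == nothing or Q2 == no        -> no_experience
4. else                                  -> no_information

A Q1-positive report paired with Q2 == "no" is classed *experience*
(detail recalled outweighs the denial); an uncertain "maybe" with an
uninformative Q1 is *no_information*.  The rule is a plain
(q1, q2) -> class table, so alternative readings can be swapped in.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

Q1_CATEGORIES = ("nothing", "no_info", "white", "vague", "vivid")
Q2_CATEGORIES = ("no", "no_info", "maybe", "yes")
EXPERIENCE_CLASSES = ("experience", "no_information", "no_experience")

_Q1_POSITIVE = frozenset({"white", "vague", "vivid"})


@dataclass(frozen=True)
class AwakeningReport:
    """One awakening's categorized answers plus identifiers."""

    participant_id: str
    awakening_idx: int
    q1: str
    q2: str

    def __post_init__(self) -> None:
        if self.q1 not in Q1_CATEGORIES:
            raise ValueError(f"unknown Q1 category {self.q1!r}")
        if self.q2 not in Q2_CATEGORIES:
            raise ValueError(f"unknown Q2 answer {self.q2!r}")


class ClassificationRule:
    """A (q1, q2) -> experience-class lookup table."""

    def __init__(self, mapping: dict[tuple[str, str], str]):
        for (q1, q2), cls in mapping.items():
            if q1 not in Q1_CATEGORIES or q2 not in Q2_CATEGORIES:
                raise ValueError(f"unknown category pair ({q1!r}, {q2!r})")
            if cls not in EXPERIENCE_CLASSES:
                raise ValueError(f"unknown experience class {cls!r}")
        missing = [(a, b) for a in Q1_CATEGORIES for b in Q2_CATEGORIES
                   if (a, b) not in mapping]
        if missing:
            raise ValueError(f"rule table incomplete, missing {missing[:3]}...")
        self.mapping = dict(mapping)

    def classify(self, q1: str, q2: str) -> str:
        try:
            return self.mapping[(q1, q2)]
        except KeyError:
            raise ValueError(f"unknown category pair ({q1!r}, {q2!r})") from None


def _default_class(q1: str, q2: str) -> str:
    if q1 in _Q1_POSITIVE:
        return "experience"
    if q2 == "yes":
        return "experience"
    if q1 == "nothing" or q2 == "no":
        return "no_experience"
    return "no_information"


def default_rule() -> ClassificationRule:
    """The packaged default experience-classification rule."""
    return ClassificationRule({
        (q1, q2): _default_class(q1, q2)
        for q1 in Q1_CATEGORIES for q2 in Q2_CATEGORIES
    })


def classify_awakening(report: AwakeningReport,
                       rule: ClassificationRule | None = None) -> str:
    """Experience class of a single awakening under ``rule``."""
    rule = rule if rule is not None else default_rule()
    return rule.classify(report.q1, report.q2)


@dataclass
class ReportTabulation:
    """Marginal counts of a list of awakening reports."""

    q1_counts: dict[str, int]
    q2_counts: dict[str, int]
    class_counts: dict[str, int]
    n_awakenings: int

    def to_frame(self) -> pd.DataFrame:
        rows = ([("q1", k, v) for k, v in self.q1_counts.items()]
                + [("q2", k, v) for k, v in self.q2_counts.items()]
                + [("class", k, v) for k, v in self.class_counts.items()])
        return pd.DataFrame(rows, columns=["axis", "category", "count"])


def tabulate(reports: list[AwakeningReport],
             rule: ClassificationRule | None = None) -> ReportTabulation:
    """Q1 / Q2 / class marginal counts for a list of reports."""
    if not reports:
        raise ValueError("empty report list")
    rule = rule if rule is not None else default_rule()
    q1 = Counter(r.q1 for r in reports)
    q2 = Counter(r.q2 for r in reports)
    cls = Counter(rule.classify(r.q1, r.q2) for r in reports)
    return ReportTabulation(
        q1_counts={k: q1.get(k, 0) for k in Q1_CATEGORIES},
        q2_counts={k: q2.get(k, 0) for k in Q2_CATEGORIES},
        class_counts={k: cls.get(k, 0) for k in EXPERIENCE_CLASSES},
        n_awakenings=len(reports),
    )


def reports_to_frame(reports: list[AwakeningReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.participant_id, r.awakening_idx, r.q1, r.q2) for r in reports],
        columns=["participant_id", "awakening_idx", "q1_category", "q2_answer"],
    )


def write_reports_csv(reports: list[AwakeningReport], path) -> None:
    reports_to_frame(reports).to_csv(path, index=False)


def read_reports_csv(path) -> list[AwakeningReport]:
    df = pd.read_csv(path)
    required = {"participant_id", "awakening_idx", "q1_category", "q2_answer"}
    if not required.issubset(df.columns):
        raise ValueError(f"report CSV must have columns {sorted(required)}")
    return [
        AwakeningReport(str(row.participant_id), int(row.awakening_idx),
                        str(row.q1_category), str(row.q2_answer))
        for row in df.itertuples()
    ]
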