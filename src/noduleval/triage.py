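"""Keyword "soft label" triage of free-text radiology reports.

A rule list is scanned in order against each report; the first phrase found
(case-insensitive literal substring, after whitespace/hyphen normalization)
assigns its label and decides inclusion or exclusion. Reports matching no
rule stay unlabeled. This reproduces a cohort-selection filter in which
studies with confounding findings (consolidation, sizeable pleural effusion,
emphysematous change, architectural distortion, prior surgery) are excluded
before nodule-mention keywords select the candidate cohort; the final
human confirmation step is out of scope, but the audit log supports it.

No negation or uncertainty detection is attempted: "no consolidation" is
excluded like "dense consolidation". Rules are fully user-overridable, and a
regex escape hatch (``phrase`` starting with ``re:``) is provided.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


class TriageConfigError(ValueError):
    """The rule list or sampling request is unusable."""


@dataclass(frozen=True)
class LabelRule:
    ordinal: int
    phrase: str
    label: str
    polarity: str  # "exclusion" | "inclusion"

    def __post_init__(self) -> None:
        if not self.phrase.strip():
            raise TriageConfigError("empty phrase in rule list")
        if self.polarity not in ("exclusion", "inclusion"):
            raise TriageConfigError(f"unknown polarity {self.polarity!r}")


@dataclass(frozen=True)
class TriageResult:
    study_id: str
    decision: str  # "excluded" | "included" | "unlabeled"
    soft_label: Optional[str] = None
    matched_phrase: Optional[str] = None


def _normalize(text: str) -> str:
    return re.sub(r"\s+", " ", text.lower().replace("-", " ")).strip()


def default_rules() -> List[LabelRule]:
    """Built-in rule list: five exclusion families first, then the three
    nodule-composition inclusion keywords. Editorial phrase variants; meant
    to be overridden with site-specific wording."""
    exclusions = [
        ("consolidation", ["consolidation"]),
        (
            "pleural effusion",
            ["moderate pleural effusion", "severe pleural effusion", "large pleural effusion"],
        ),
        ("emphysema", ["emphysematous", "emphysema"]),
        ("architectural distortion", ["architectural distortion"]),
        (
            "surgery",
            ["surgery", "surgical", "post surgical", "lobectomy", "pneumonectomy"],
        ),
    ]
    inclusions = [
        ("part-solid", ["part solid nodule", "part solid pulmonary nodule"]),
        ("ground glass", ["ground glass nodule", "ground glass opacity nodule"]),
        ("solid", ["solid nodule", "solid pulmonary nodule", "lung nodule", "pulmonary nodule"]),
    ]
    rules: List[LabelRule] = []
    ordinal = 0
    for label, phrases in exclusions:
        for phrase in phrases:
            rules.append(LabelRule(ordinal, phrase, label, "exclusion"))
            ordinal += 1
    for label, phrases in inclusions:
        for phrase in phrases:
            rules.append(LabelRule(ordinal, phrase, label, "inclusion"))
            ordinal += 1
    return rules


def _rule_matches(rule: LabelRule, normalized_text: str) -> bool:
    if rule.phrase.startswith("re:"):
        return re.search(rule.phrase[3:], normalized_text) is not None
    return _normalize(rule.phrase) in normalized_text


def apply_rules(
    study_id: str, report_text: str, rules: Sequence[LabelRule]
) -> TriageResult:
    """First-match-wins rule scan over one report."""
    if not rules:
        raise TriageConfigError("rule list is empty")
    ordinals = [r.ordinal for r in rules]
    if len(set(ordinals)) != len(ordinals):
        raise TriageConfigError("rule ordinals must be unique")
    normalized = _normalize(report_text or "")
    for rule in sorted(rules, key=lambda r: r.ordinal):
        if _rule_matches(rule, normalized):
            decision = "excluded" if rule.polarity == "exclusion" else "included"
            return TriageResult(
                study_id=study_id,
                decision=decision,
                soft_label=rule.label,
                matched_phrase=rule.phrase,
            )
    return TriageResult(study_id=study_id, decision="unlabeled")


def triage_cohort(
    reports: Dict[str, str],
    rules: Sequence[LabelRule],
    target_n: int,
    seed: int,
) -> Tuple[List[str], pd.DataFrame]:
    """Label every report and uniformly sample ``target_n`` included studies.

    ``reports`` maps study_id -> report text. Returns the sorted selected
    cohort and an audit log (one row per report, every decision recorded).
    """
    results = [
        apply_rules(study_id, text, rules) for study_id, text in sorted(reports.items())
    ]
    audit = pd.DataFrame(
        {
            "study_id": [r.study_id for r in results],
            "decision": [r.decision for r in results],
            "soft_label": [r.soft_label for r in results],
            "matched_phrase": [r.matched_phrase for r in results],
        }
    )
    included = [r.study_id for r in results if r.decision == "included"]
    if target_n > len(included):
        raise TriageConfigError(
            f"requested {target_n} studies but only {len(included)} were included "
            f"(shortfall {target_n - len(included)})"
        )
    rng = np.random.default_rng(seed)
    selected = sorted(rng.choice(included, size=target_n, replace=False).tolist())
    audit["selected"] = audit["study_id"].isin(selected)
    return selected, audit


def rules_from_frame(frame: pd.DataFrame) -> List[LabelRule]:
    """Build a rule list from a config table with columns
    ordinal, phrase, label, polarity."""
    required = {"ordinal", "phrase", "label", "polarity"}
    if not required.issubset(frame.columns):
        raise TriageConfigError(f"rules table needs columns {sorted(required)}")
    return [
        LabelRule(int(row.ordinal), str(row.phrase), str(row.label), str(row.polarity))
        for row in frame.itertuples()
    ]
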