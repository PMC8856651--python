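"""ACMG/ClinGen evidence combination into a five-tier verdict.

Evidence items are coded criteria (PS3, PM2, PP1, ...) carrying a direction
(pathogenic or benign) and a strength (stand-alone, very strong, strong,
moderate, supporting). Strengths may be modified relative to a code's default
— notably PP1, whose strength scales with the co-segregation LOD score (the
strong tier requires LOD > 3). The combining rules are shipped as an editable
JSON table (``data/acmg_rules.json``) evaluated over counts of evidence items
per (direction, strength); guideline revisions therefore never require code
changes.
"""

from __future__ import annotations

import importlib.resources
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import ConfigurationError, ValidationError

STRENGTHS = ("stand_alone", "very_strong", "strong", "moderate", "supporting")
VERDICTS = ("pathogenic", "likely_pathogenic", "uncertain_significance",
            "likely_benign", "benign")

#: Default (direction, strength) per ACMG 2015 code family.
CODE_DEFAULTS: dict[str, tuple[str, str]] = {}
CODE_DEFAULTS["PVS1"] = ("pathogenic", "very_strong")
for _c in ("PS1", "PS2", "PS3", "PS4"):
    CODE_DEFAULTS[_c] = ("pathogenic", "strong")
for _c in ("PM1", "PM2", "PM3", "PM4", "PM5", "PM6"):
    CODE_DEFAULTS[_c] = ("pathogenic", "moderate")
for _c in ("PP1", "PP2", "PP3", "PP4", "PP5"):
    CODE_DEFAULTS[_c] = ("pathogenic", "supporting")
CODE_DEFAULTS["BA1"] = ("benign", "stand_alone")
for _c in ("BS1", "BS2", "BS3", "BS4"):
    CODE_DEFAULTS[_c] = ("benign", "strong")
for _c in ("BP1", "BP2", "BP3", "BP4", "BP5", "BP6", "BP7"):
    CODE_DEFAULTS[_c] = ("benign", "supporting")


@dataclass(frozen=True)
class EvidenceItem:
    code: str
    strength: str
    direction: str
    note: str = ""

    def __post_init__(self):
        if self.strength not in STRENGTHS:
            raise ValidationError(f"unknown strength {self.strength!r}")
        if self.direction not in ("pathogenic", "benign"):
            raise ValidationError(f"unknown direction {self.direction!r}")


def evidence(code: str, strength: str | None = None, note: str = "") -> EvidenceItem:
    """Build an :class:`EvidenceItem` from a code, using the code's default
    direction and (unless overridden) default strength.

    Unknown codes must declare strength and direction explicitly via
    :class:`EvidenceItem`.
    """
    if code not in CODE_DEFAULTS:
        raise ValidationError(
            f"unknown ACMG code {code!r}: construct EvidenceItem with explicit "
            "strength and direction"
        )
    direction, default_strength = CODE_DEFAULTS[code]
    return EvidenceItem(code=code, strength=strength or default_strength,
                        direction=direction, note=note)


@dataclass
class Classification:
    verdict: str
    fired_rule: str
    evidence: list[EvidenceItem] = field(default_factory=list)


#: Default PP1 strength thresholds on the maximum LOD score. Only the strong
#: tier (LOD > 3, strict) is anchored to the study's stated rule; the lower
#: tiers follow common co-segregation practice and are configurable.
DEFAULT_PP1_THRESHOLDS: dict[str, float] = {
    "supporting": 0.6,
    "moderate": 1.5,
    "strong": 3.0,
}


def pp1_strength(
    lod_max: float,
    thresholds: Mapping[str, float] = DEFAULT_PP1_THRESHOLDS,
) -> EvidenceItem | None:
    """Map a maximum LOD score to PP1 co-segregation evidence.

    Returns PP1 at the highest strength whose threshold is met, or ``None``
    below the supporting threshold. The strong tier uses a strict inequality
    (LOD > threshold); lower tiers are inclusive. Thresholds must increase
    with strength.
    """
    order = [s for s in ("supporting", "moderate", "strong", "very_strong")
             if s in thresholds]
    values = [thresholds[s] for s in order]
    if any(b <= a for a, b in zip(values, values[1:])):
        raise ConfigurationError(
            f"PP1 thresholds must be strictly increasing with strength: {thresholds}"
        )
    chosen = None
    for s in order:
        t = thresholds[s]
        met = lod_max > t if s in ("strong", "very_strong") else lod_max >= t
        if met:
            chosen = s
    if chosen is None:
        return None
    return evidence("PP1", strength=chosen,
                    note=f"co-segregation LOD {lod_max:.3f}")


def load_rules(path: str | Path | None = None) -> dict:
    if path is None:
        resource = importlib.resources.files("famseg") / "data" / "acmg_rules.json"
        return json.loads(resource.read_text())
    return json.loads(Path(path).read_text())


def _counts(evidence_items: Iterable[EvidenceItem], direction: str) -> Counter:
    return Counter(e.strength for e in evidence_items if e.direction == direction)


def _first_match(rules: list[dict], counts: Counter) -> dict | None:
    for rule in rules:
        if all(counts.get(strength, 0) >= minimum
               for strength, minimum in rule["min_counts"].items()):
            return rule
    return None


def combine(evidence_items: Iterable[EvidenceItem], rules: dict | None = None) -> Classification:
    """Apply the combining-rule table to a list of evidence items.

    Pathogenic-direction and benign-direction rules are evaluated separately;
    a match on both sides is a conflict and yields uncertain significance, as
    does no match on either side.
    """
    items = list(evidence_items)
    table = rules if rules is not None else load_rules()
    path_counts = _counts(items, "pathogenic")
    benign_counts = _counts(items, "benign")

    path_rule = (_first_match(table["pathogenic"], path_counts)
                 or _first_match(table["likely_pathogenic"], path_counts))
    path_verdict = None
    if path_rule is not None:
        path_verdict = ("pathogenic"
                        if path_rule in table["pathogenic"] else "likely_pathogenic")
    benign_rule = (_first_match(table["benign"], benign_counts)
                   or _first_match(table["likely_benign"], benign_counts))
    benign_verdict = None
    if benign_rule is not None:
        benign_verdict = ("benign"
                          if benign_rule in table["benign"] else "likely_benign")

    if path_verdict and benign_verdict:
        return Classification("uncertain_significance",
                              "conflict: pathogenic and benign rules both met", items)
    if path_verdict:
        return Classification(path_verdict,
                              f"{path_rule['id']}: {path_rule['desc']}", items)
    if benign_verdict:
        return Classification(benign_verdict,
                              f"{benign_rule['id']}: {benign_rule['desc']}", items)
    return Classification("uncertain_significance", "no combining rule met", items)


def replay_rule(classification: Classification, rules: dict | None = None) -> str:
    """Re-evaluate a classification's evidence against the rule table.

    Round-trip check: the verdict obtained from the evidence alone must equal
    the recorded verdict.
    """
    return combine(classification.evidence, rules=rules).verdict
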