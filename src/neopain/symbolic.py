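"""Symbolic explanation engine with three-tier conflict resolution.

The rule base holds 18 rules in four categories — high-confidence pain (6),
moderate pain (5), ambiguous (4) and no-pain baseline (3) — mapped to three
priority tiers:

* **Tier 1 (physiological override):** a cross-modal high-confidence rule
  fires -> emit the highest-weight firing Tier-1 rule's assessment
  immediately, overriding everything else.
* **Tier 2 (symbolic consensus):** otherwise, a weighted vote over firing
  moderate-pain rules picks the level (ties break toward higher severity).
* **Tier 3 (uncertainty escalation):** otherwise the evidential uncertainty
  ``u`` is elevated by a configured increment; if the elevated ``u``
  exceeds 0.5 the system abstains ("Clinician review required"), else it
  reports the no-pain baseline.

Guard predicates compare concept activations to their GA-resolved
thresholds with strict inequalities; a guard touching an unavailable
concept prevents its rule from firing, so the engine is a pure function of
(available) concepts, context and ``u``.

For ventilated (intubated) infants a dedicated protocol applies before rule
evaluation: audio concepts C5-C8 are suppressed entirely, physiological
activations C9-C12 are up-weighted 1.5x (clamped to [0, 1]), a 6-rule
ventilation subset replaces the standard 18 rules, and ``u`` is elevated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .concepts import (CONCEPT_IDS, FACIAL, ConceptVector, ThresholdTable,
                       ga_stratum)
from .errors import ValidationError

UNCERTAINTY_INCREMENT = 0.1
ABSTAIN_RECOMMENDATION = "Clinician review required"
CATEGORY_TIER = {"high_confidence": 1, "moderate": 2,
                 "ambiguous": 3, "no_pain": 3}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Rule:
    rule_id: str
    tier: int
    category: str
    weight: float
    pain_level: int
    guard: tuple              # of (concept_id, above: bool)
    explanation: str
    recommendation: str


@dataclass
class RuleSet:
    rules: list[Rule]

    def __post_init__(self) -> None:
        ids = [r.rule_id for r in self.rules]
        if len(set(ids)) != len(ids):
            raise ValidationError("rules", "duplicate rule ids")
        for r in self.rules:
            if r.tier not in (1, 2, 3):
                raise ValidationError(r.rule_id, f"bad tier {r.tier}")
            if r.category not in CATEGORY_TIER:
                raise ValidationError(r.rule_id, f"unknown category {r.category}")
            if CATEGORY_TIER[r.category] != r.tier:
                raise ValidationError(
                    r.rule_id, f"category {r.category} must be tier "
                    f"{CATEGORY_TIER[r.category]}")
            if r.weight <= 0:
                raise ValidationError(r.rule_id, "weight must be positive")
            if r.pain_level not in (0, 1, 2, 3):
                raise ValidationError(r.rule_id, f"bad pain level {r.pain_level}")
            for cid, _ in r.guard:
                if cid not in CONCEPT_IDS:
                    raise ValidationError(r.rule_id, f"unknown concept {cid}")

    def tier_rules(self, tier: int) -> list[Rule]:
        return [r for r in self.rules if r.tier == tier]

    def category_counts(self) -> dict:
        out: dict[str, int] = {}
        for r in self.rules:
            out[r.category] = out.get(r.category, 0) + 1
        return out


@dataclass
class Assessment:
    """Final symbolic output: a pain level or an abstention, with tier,
    human-readable explanation and recommendation."""

    pain_level: int | None
    abstained: bool
    tier: int
    explanation: str
    recommendation: str
    fired_rule_ids: list[str] = field(default_factory=list)
    u_final: float = 0.0
    tie_flag: bool = False

    def __post_init__(self) -> None:
        if self.abstained == (self.pain_level is not None):
            raise ValidationError(
                "assessment", "exactly one of pain_level / abstained must be set")
        if self.abstained and self.recommendation != ABSTAIN_RECOMMENDATION:
            raise ValidationError("recommendation",
                                  f"abstention requires '{ABSTAIN_RECOMMENDATION}'")

    def to_dict(self) -> dict:
        return {"pain_level": self.pain_level, "abstained": self.abstained,
                "tier": self.tier, "explanation": self.explanation,
                "recommendation": self.recommendation,
                "fired_rule_ids": self.fired_rule_ids,
                "u_final": self.u_final, "tie_flag": self.tie_flag}


# ---------------------------------------------------------------------------
# rule loading
# ---------------------------------------------------------------------------

def _parse_rules(entries: list[dict]) -> list[Rule]:
    rules = []
    for e in entries:
        guard = tuple((g["concept"], bool(g["above"])) for g in e["guard"])
        rules.append(Rule(rule_id=e["id"], tier=int(e["tier"]),
                          category=e["category"], weight=float(e["weight"]),
                          pain_level=int(e["pain_level"]), guard=guard,
                          explanation=e["explanation"],
                          recommendation=e["recommendation"]))
    return rules


def build_default_ruleset() -> tuple[RuleSet, RuleSet]:
    """The packaged (standard 18-rule, ventilated 6-rule) rule sets."""
    text = resources.files("neopain.data").joinpath("rules.yaml").read_text()
    raw = yaml.safe_load(text)
    return RuleSet(_parse_rules(raw["rules"])), \
        RuleSet(_parse_rules(raw["ventilated_rules"]))


def load_ruleset(path) -> tuple[RuleSet, RuleSet]:
    """Load a user rules file (same YAML schema as the packaged default);
    validation errors name the offending rule."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    standard = RuleSet(_parse_rules(raw["rules"]))
    vent = RuleSet(_parse_rules(raw.get("ventilated_rules", [])))
    return standard, vent


# ---------------------------------------------------------------------------
# threshold resolution for rule guards
# ---------------------------------------------------------------------------

def rule_thresholds(table: ThresholdTable | None = None,
                    ga_weeks: float | None = None) -> dict:
    """Activation-scale guard thresholds per concept.

    Facial concepts use the GA-stratified values (or the flat 0.70 default
    when GA is unknown). Cry intensity (C5) and HR acceleration (C9) use the
    flat engine defaults (0.60, 0.50). All remaining concepts use 0.5 —
    which on the logistic-margin activation scale is exactly the clinical
    firing rule.
    """
    table = table or ThresholdTable.default()
    flat = table.flat_defaults
    out = {cid: 0.5 for cid in CONCEPT_IDS}
    for cid in FACIAL:
        if ga_weeks is None:
            out[cid] = flat.get("brow", 0.7)
        else:
            out[cid] = table.concept(cid)["by_stratum"][ga_stratum(ga_weeks)]
    out["C5"] = flat.get("cry", 0.6)
    out["C9"] = flat.get("hr", 0.5)
    return out


# ---------------------------------------------------------------------------
# engine operations
# ---------------------------------------------------------------------------

def evaluate_rules(concepts: ConceptVector, thresholds: dict,
                   ruleset: RuleSet) -> list[Rule]:
    """Rules whose every guard predicate holds on available concepts
    (strict comparisons); unavailable concepts block their rules."""
    idx = {cid: k for k, cid in enumerate(CONCEPT_IDS)}
    fired = []
    for rule in ruleset.rules:
        ok = True
        for cid, above in rule.guard:
            k = idx[cid]
            if not concepts.available[k]:
                ok = False
                break
            act, tau = concepts.activations[k], thresholds[cid]
            if above and not (act > tau):
                ok = False
                break
            if not above and not (act < tau):
                ok = False
                break
        if ok:
            fired.append(rule)
    return fired


def resolve_tiers(fired_rules: list[Rule], u: float,
                  increment: float = UNCERTAINTY_INCREMENT) -> Assessment:
    """Three-tier priority resolution of the firing rules."""
    fired_ids = [r.rule_id for r in fired_rules]
    tier1 = [r for r in fired_rules if r.tier == 1]
    if tier1:
        best = max(tier1, key=lambda r: (r.weight, r.pain_level))
        return Assessment(pain_level=best.pain_level, abstained=False, tier=1,
                          explanation=best.explanation,
                          recommendation=best.recommendation,
                          fired_rule_ids=fired_ids, u_final=u)
    tier2 = [r for r in fired_rules if r.tier == 2]
    if tier2:
        votes = np.zeros(4)
        for r in tier2:
            votes[r.pain_level] += r.weight
        best_vote = votes.max()
        winners = np.where(votes == best_vote)[0]
        level = int(winners[-1])            # ties toward higher severity
        supporting = [r for r in tier2 if r.pain_level == level]
        lead = max(supporting, key=lambda r: r.weight)
        return Assessment(pain_level=level, abstained=False, tier=2,
                          explanation="; ".join(r.explanation for r in supporting),
                          recommendation=lead.recommendation,
                          fired_rule_ids=fired_ids, u_final=u,
                          tie_flag=len(winners) > 1)
    # Tier 3: elevate u, then abstain or report the no-pain baseline
    u_final = min(1.0, u + increment)
    tier3 = [r for r in fired_rules if r.tier == 3]
    ambiguous = [r for r in tier3 if r.category == "ambiguous"]
    if u_final > 0.5:
        expl = ("; ".join(r.explanation for r in ambiguous)
                or "Conflicting or sub-threshold indicators")
        return Assessment(pain_level=None, abstained=True, tier=3,
                          explanation=expl,
                          recommendation=ABSTAIN_RECOMMENDATION,
                          fired_rule_ids=fired_ids, u_final=u_final)
    baseline = [r for r in tier3 if r.category == "no_pain"]
    expl = ("; ".join(r.explanation for r in (ambiguous or baseline))
            or "No indicator exceeded threshold")
    rec = baseline[0].recommendation if baseline else "Routine monitoring"
    return Assessment(pain_level=0, abstained=False, tier=3, explanation=expl,
                      recommendation=rec, fired_rule_ids=fired_ids,
                      u_final=u_final)


def apply_ventilation_protocol(concepts: ConceptVector, ventilated: bool,
                               increment: float = UNCERTAINTY_INCREMENT
                               ) -> tuple[ConceptVector, str, float]:
    """Ventilation-flag protocol: suppress audio concepts, up-weight
    physiological ones 1.5x (clamped), select the ventilation rule subset
    and return the uncertainty increment to apply. Identity when not
    ventilated."""
    if not ventilated:
        return concepts, "standard", 0.0
    out = concepts.copy()
    out.available[4:8] = False
    out.fired[4:8] = False
    out.activations[8:12] = np.clip(out.activations[8:12] * 1.5, 0.0, 1.0)
    out.fired[8:12] = out.fired[8:12] | (
        out.available[8:12] & (out.activations[8:12] > 0.5))
    return out, "ventilated", increment


def assess(concepts: ConceptVector, *, ga_weeks: float | None = None,
           ventilated: bool = False, u: float = 0.0,
           table: ThresholdTable | None = None,
           rulesets: tuple[RuleSet, RuleSet] | None = None,
           increment: float = UNCERTAINTY_INCREMENT) -> Assessment:
    """End-to-end symbolic assessment of one concept vector.

    A pure deterministic function of its inputs: applies the ventilation
    protocol, evaluates the selected rule set against GA-resolved guard
    thresholds, and resolves tiers against the evidential uncertainty."""
    table = table or ThresholdTable.default()
    standard, vent = rulesets if rulesets is not None else build_default_ruleset()
    concepts, selector, bump = apply_ventilation_protocol(
        concepts, ventilated, increment)
    u = min(1.0, u + bump)
    ruleset = vent if selector == "ventilated" else standard
    thresholds = rule_thresholds(table, ga_weeks)
    fired = evaluate_rules(concepts, thresholds, ruleset)
    return resolve_tiers(fired, u, increment)
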