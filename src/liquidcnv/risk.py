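"""Three-class myeloid cytogenetic risk rule engine.

Maps an :class:`~liquidcnv.iscn.ImbalanceSet` — from either a parsed
karyotype or NGS copy-number shorthand — to a prognostic class through an
ordered, first-match-wins rule table.  The default table encodes the
conventions of myeloid (MDS/AML) cytogenetic risk grouping at the resolution
dosage data supports: a complex pattern of co-occurring abnormalities,
adverse single markers (chromosome 7 loss, 17p/TP53-region loss,
amplification or marker chromosomes, biallelic CDKN2A/B loss on 9p), any
other clonal imbalance as intermediate, and a normal result as intermediate.
The complex-vs-poor boundary is configuration, not a biological claim:
published per-case labels are not consistent with any single counting rule,
so the threshold and the weight of dosage-indeterminate abnormalities are
exposed in the rules file.
"""

from __future__ import annotations

import enum
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import yaml

from .iscn import ImbalanceSet


class RiskClass(str, enum.Enum):
    NOT_EVALUABLE = "not evaluable"
    NO_LOSS_GAIN = "no loss/gain"
    INTERMEDIATE = "intermediate"
    POOR = "poor"
    COMPLEX = "complex"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class RuleConfigError(ValueError):
    """Raised for malformed rule configurations."""


#: genes whose annotated 9p loss is an adverse marker
_POOR_9P_GENES = {"CDKN2A", "CDKN2B", "CDKN2A/B"}


def _not_evaluable(imb: ImbalanceSet, params: dict) -> bool:
    return not imb.evaluable


def _fusion_only(imb: ImbalanceSet, params: dict) -> bool:
    return imb.fusion_only


def _complexity(imb: ImbalanceSet, params: dict) -> bool:
    weight = float(params.get("indeterminate_weight", 1.0))
    score = imb.determinate_count + weight * imb.indeterminate_count
    return score >= float(params.get("complex_min", 3))


def _poor_region(imb: ImbalanceSet, params: dict) -> bool:
    if imb.has_loss("7", "chrom") or imb.has_loss("7", "q"):
        return True
    if imb.has_loss("17", "p"):
        return True
    if imb.has_amplification():
        return True
    for i in imb.determinate:
        if (
            i.chrom == "9"
            and i.region == "p"
            and i.direction == "loss"
            and set(i.genes) & _POOR_9P_GENES
        ):
            return True
    return False


def _any_abnormality(imb: ImbalanceSet, params: dict) -> bool:
    return imb.determinate_count + imb.indeterminate_count >= 1


def _default(imb: ImbalanceSet, params: dict) -> bool:
    return True


PREDICATES: dict[str, Callable[[ImbalanceSet, dict], bool]] = {
    "not_evaluable": _not_evaluable,
    "fusion_only": _fusion_only,
    "complexity": _complexity,
    "poor_region": _poor_region,
    "any_abnormality": _any_abnormality,
    "default": _default,
}


@dataclass(frozen=True)
class RiskRule:
    predicate: str
    result: RiskClass
    params: dict = field(default_factory=dict)

    def matches(self, imb: ImbalanceSet) -> bool:
        return PREDICATES[self.predicate](imb, self.params)


@dataclass(frozen=True)
class RiskRuleSet:
    rules: tuple[RiskRule, ...]

    def __post_init__(self) -> None:
        if not self.rules:
            raise RuleConfigError("rule list must not be empty")
        for r in self.rules:
            if r.predicate not in PREDICATES:
                raise RuleConfigError(f"unknown predicate {r.predicate!r}")
        if self.rules[-1].predicate != "default":
            raise RuleConfigError("rule set must end with a default clause")


def classify(imbalances: ImbalanceSet, rules: Optional[RiskRuleSet] = None) -> RiskClass:
    """First matching rule's class; total by construction (default clause)."""
    if rules is None:
        rules = default_rules()
    for rule in rules.rules:
        if rule.matches(imbalances):
            return rule.result
    raise AssertionError("unreachable: rule set validated to end with default")


def load_rules(path: str | Path) -> RiskRuleSet:
    """Load an ordered rule table from YAML.

    Top-level ``complex_min`` and ``indeterminate_weight`` are folded into
    every complexity rule's parameters; unknown predicates and a missing
    default clause are configuration errors.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _rules_from_doc(doc, source=str(path))


def _rules_from_doc(doc: dict, source: str = "<config>") -> RiskRuleSet:
    if not isinstance(doc, dict) or "rules" not in doc:
        raise RuleConfigError(f"{source}: expected a mapping with a 'rules' list")
    shared = {
        k: doc[k] for k in ("complex_min", "indeterminate_weight") if k in doc
    }
    rules = []
    for entry in doc["rules"] or []:
        try:
            predicate = entry["predicate"]
            result = RiskClass[entry["class"]]
        except (KeyError, TypeError) as exc:
            raise RuleConfigError(f"{source}: malformed rule entry {entry!r}") from exc
        params = dict(shared)
        params.update(entry.get("params", {}))
        rules.append(RiskRule(predicate, result, params))
    return RiskRuleSet(tuple(rules))


_DEFAULT_CACHE: Optional[RiskRuleSet] = None


def default_rules() -> RiskRuleSet:
    """The packaged default rule table (see ``data/rules.yaml``)."""
    global _DEFAULT_CACHE
    if _DEFAULT_CACHE is None:
        ref = importlib.resources.files("liquidcnv.data").joinpath("rules.yaml")
        doc = yaml.safe_load(ref.read_text())
        _DEFAULT_CACHE = _rules_from_doc(doc, source="packaged rules.yaml")
    return _DEFAULT_CACHE
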