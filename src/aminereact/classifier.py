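"""Rules-based reactivity classification of amine sites.

The decision tree maps a site's five structural parameters to one of
three classes, evaluated strictly in order:

1. ESA < 50 Å²           -> non_reacting   (buried amine)
2. pKa > 10.3            -> slow_reacting  (protonated at reaction pH)
3. helix                 -> slow_reacting  (less accessible fold)
4. H-bond donor          -> slow_reacting  (amine sequestered)
5. low positive charge   -> fast_reacting, otherwise slow_reacting

Boundary semantics: ESA exactly 50 Å² is reactive (the non-reacting
test is strict '<'); pKa exactly 10.3 passes the fast branch (the
slow test is strict '>').  Branches 1-3 are anchored in reported
behaviour of the reference protocol; the order and direction of
branches 4-5 are this module's reconstruction and can be overridden by
a plain-text rules file, so a corrected tree can be swapped in without
code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .config import ClassifierThresholds
from .errors import ClassificationError, ConfigurationError
from .structure_io import AmineSite

NON_REACTING = "non_reacting"
SLOW_REACTING = "slow_reacting"
FAST_REACTING = "fast_reacting"
CLASSES = (NON_REACTING, SLOW_REACTING, FAST_REACTING)


@dataclass
class SiteParameters:
    """The five predictors of one amine site."""

    site: Optional[AmineSite]
    esa: float  # Å²
    pka: float
    ss3: str  # helix | strand | coil
    h_donor: bool
    coulomb_energy: float  # kcal/mol
    low_positive_charge: bool

    def validate(self) -> None:
        for name in ("esa", "pka", "ss3", "h_donor", "low_positive_charge"):
            if getattr(self, name) is None:
                raise ClassificationError(f"parameter {name!r} missing for "
                                          f"{self.site.site_id if self.site else '?'}")
        if self.esa < 0:
            raise ClassificationError("esa must be >= 0")
        if self.ss3 not in ("helix", "strand", "coil"):
            raise ClassificationError(f"unknown ss3 value {self.ss3!r}")


@dataclass
class ReactivityClass:
    """Decision-tree output with the audit trail of branches taken."""

    label: str
    rule_path: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class Rule:
    """One ordered branch: if `condition` holds, classify as `outcome`."""

    condition: str  # esa_low | pka_high | helix | h_donor | low_positive_charge | else
    outcome: str

    def test(self, p: SiteParameters, thr: ClassifierThresholds) -> bool:
        if self.condition == "esa_low":
            return p.esa < thr.esa_reactive
        if self.condition == "pka_high":
            return p.pka > thr.pka_branch
        if self.condition == "helix":
            return p.ss3 == "helix"
        if self.condition == "h_donor":
            return p.h_donor
        if self.condition == "low_positive_charge":
            return p.low_positive_charge
        if self.condition == "else":
            return True
        raise ConfigurationError(f"unknown rule condition {self.condition!r}")


DEFAULT_RULES: tuple[Rule, ...] = (
    Rule("esa_low", NON_REACTING),
    Rule("pka_high", SLOW_REACTING),
    Rule("helix", SLOW_REACTING),
    Rule("h_donor", SLOW_REACTING),
    Rule("low_positive_charge", FAST_REACTING),
    Rule("else", SLOW_REACTING),
)


def classify_site(params: SiteParameters,
                  thresholds: ClassifierThresholds | None = None,
                  rules: Sequence[Rule] = DEFAULT_RULES) -> ReactivityClass:
    """Apply the (possibly overridden) decision tree to one site."""
    thr = thresholds or ClassifierThresholds()
    params.validate()
    path: list[str] = []
    for rule in rules:
        hit = rule.test(params, thr)
        path.append(f"{rule.condition}={'yes' if hit else 'no'}")
        if hit:
            if rule.outcome not in CLASSES:
                raise ConfigurationError(f"unknown outcome {rule.outcome!r}")
            return ReactivityClass(label=rule.outcome, rule_path=path)
    raise ConfigurationError("rule set is not total: add a final 'else' rule")


def save_rules(rules: Sequence[Rule], path: str | Path) -> None:
    """Serialize rules as ordered 'condition => outcome' lines."""
    lines = [f"{r.condition} => {r.outcome}" for r in rules]
    Path(path).write_text("\n".join(lines) + "\n")


def load_rules(path: str | Path) -> list[Rule]:
    rules: list[Rule] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=>" not in line:
            raise ConfigurationError(f"{path}:{lineno}: expected 'condition => outcome'")
        cond, outcome = (s.strip() for s in line.split("=>", 1))
        if outcome not in CLASSES:
            raise ConfigurationError(f"{path}:{lineno}: unknown outcome {outcome!r}")
        rules.append(Rule(cond, outcome))
    if not rules or rules[-1].condition != "else":
        raise ConfigurationError(f"{path}: rule set must end with an 'else' rule")
    return rules
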