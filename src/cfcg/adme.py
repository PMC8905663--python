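"""Rule-of-five (Lipinski) screening of candidate components.

A component is drug-like when all five criteria hold, each with a strict
inequality: MW < 500 Da, rotatable bonds < 11, H-bond acceptors < 10,
H-bond donors < 5 and −2 < ClogP < 5.  A record exactly at a threshold
fails that rule.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

from .io_core import ComponentRecord

__all__ = ["RULES", "ScreenReport", "passes_rule_of_five", "screen_components"]

# rule name -> predicate on the record
RULES = {
    "mw<500": lambda r: r.mw < 500.0,
    "rbn<11": lambda r: r.rbn < 11,
    "nhacc<10": lambda r: r.n_hacc < 10,
    "nhdon<5": lambda r: r.n_hdon < 5,
    "-2<clogp<5": lambda r: -2.0 < r.clogp < 5.0,
}


@dataclass
class ScreenReport:
    """Summary counts for one screening pass."""

    n_input: int = 0
    n_passed: int = 0
    rule_failures: Counter = field(default_factory=Counter)  # rule -> count
    herb_passed: Counter = field(default_factory=Counter)  # herb -> passed memberships

    @property
    def n_failed(self) -> int:
        return self.n_input - self.n_passed

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_passed": self.n_passed,
            "n_failed": self.n_failed,
            "rule_failures": dict(sorted(self.rule_failures.items())),
            "herb_passed": dict(sorted(self.herb_passed.items())),
        }


def passes_rule_of_five(rec: ComponentRecord) -> tuple[bool, list[str]]:
    """Apply the five strict criteria; return (passed, failed rule names)."""
    for fname in ("mw", "clogp"):
        if not math.isfinite(getattr(rec, fname)):
            raise ValueError(f"{rec.component_id}: {fname} is not finite")
    failed = [name for name, ok in RULES.items() if not ok(rec)]
    return (not failed, failed)


def screen_components(
    records: list[ComponentRecord],
) -> tuple[list[ComponentRecord], ScreenReport]:
    """Filter a component list by the rule of five.

    Returns the passing records in input order plus a :class:`ScreenReport`.
    A multi-herb component counts once in ``n_passed`` but contributes one
    membership to each of its herbs in ``herb_passed``.
    """
    report = ScreenReport(n_input=len(records))
    passed: list[ComponentRecord] = []
    for rec in records:
        ok, failed = passes_rule_of_five(rec)
        if ok:
            passed.append(rec)
            report.n_passed += 1
            for herb in rec.herbs:
                report.herb_passed[herb] += 1
        else:
            for rule in failed:
                report.rule_failures[rule] += 1
    return passed, report
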