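"""Drug-likeness screening of compound property tables.

The filter combines the Rule-of-Five descriptor bounds with an oral
bioavailability window and a gastrointestinal-absorption class:

* molecular weight strictly below ``mw_max`` (default 500 Da),
* H-bond donors/acceptors and rotatable bonds at or below their caps,
* logP inside the inclusive ``[logp_min, logp_max]`` window,
* bioavailability score inside the inclusive ``[0.3, 0.55]`` window,
* GI absorption class ``high`` (when required).

A compound passes only if it violates *no* rule (strict conjunction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .core import CompoundRecord


class DescriptorMissingError(ValueError):
    """A descriptor required by the screen is absent from the record."""


RULE_IDS = (
    "mw",
    "hbd",
    "hba",
    "logp",
    "rotatable_bonds",
    "bioavailability",
    "gi_absorption",
)


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds for the drug-likeness screen.

    ``mw_max`` is exclusive ("less than"); every other bound is inclusive
    ("does not exceed" / "between").
    """

    mw_max: float = 500.0
    hbd_max: int = 5
    hba_max: int = 10
    logp_min: float = -2.0
    logp_max: float = 5.0
    rotb_max: int = 10
    bioavailability_min: float = 0.3
    bioavailability_max: float = 0.55
    require_gi_high: bool = True

    def __post_init__(self) -> None:
        if self.logp_min > self.logp_max:
            raise ValueError("logp_min > logp_max")
        if self.bioavailability_min > self.bioavailability_max:
            raise ValueError("bioavailability_min > bioavailability_max")

    @classmethod
    def permissive(cls) -> "ScreenConfig":
        """No-op screen: every bound infinite, GI class not required."""
        return cls(
            mw_max=math.inf,
            hbd_max=10**9,
            hba_max=10**9,
            logp_min=-math.inf,
            logp_max=math.inf,
            rotb_max=10**9,
            bioavailability_min=0.0,
            bioavailability_max=1.0,
            require_gi_high=False,
        )


def evaluate_compound(c: CompoundRecord, cfg: ScreenConfig | None = None):
    """Evaluate one compound; returns ``(passed, violated_rule_ids)``.

    Raises :class:`DescriptorMissingError` naming the field if any required
    descriptor is absent.
    """
    cfg = cfg or ScreenConfig()
    required = ["mw", "hbd", "hba", "logp", "rotatable_bonds", "bioavailability"]
    if cfg.require_gi_high:
        required.append("gi_absorption")
    for fname in required:
        if getattr(c, fname) is None:
            raise DescriptorMissingError(
                f"compound {c.compound_id!r}: descriptor {fname!r} is missing"
            )
    violated = []
    if not c.mw < cfg.mw_max:
        violated.append("mw")
    if c.hbd > cfg.hbd_max:
        violated.append("hbd")
    if c.hba > cfg.hba_max:
        violated.append("hba")
    if not cfg.logp_min <= c.logp <= cfg.logp_max:
        violated.append("logp")
    if c.rotatable_bonds > cfg.rotb_max:
        violated.append("rotatable_bonds")
    if not cfg.bioavailability_min <= c.bioavailability <= cfg.bioavailability_max:
        violated.append("bioavailability")
    if cfg.require_gi_high and c.gi_absorption != "high":
        violated.append("gi_absorption")
    return (not violated, violated)


def screen_table(table, cfg: ScreenConfig | None = None):
    """Screen a compound table; returns ``(passed_records, rejections)``.

    ``rejections`` maps compound id -> list of violated rule ids.  The passed
    and rejected sets partition the input.
    """
    table = list(table)
    if not table:
        raise ValueError("screen_table requires a non-empty table")
    cfg = cfg or ScreenConfig()
    passed, rejections = [], {}
    for rec in table:
        ok, violated = evaluate_compound(rec, cfg)
        if ok:
            passed.append(rec)
        else:
            rejections[rec.compound_id] = violated
    return passed, rejections


def rejection_report(rejections: dict) -> pd.DataFrame:
    """Tabular rejection report: compound id plus comma-joined violated rules."""
    rows = [
        {"compound_id": cid, "violated_rules": ",".join(rules)}
        for cid, rules in sorted(rejections.items())
    ]
    return pd.DataFrame(rows, columns=["compound_id", "violated_rules"])
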