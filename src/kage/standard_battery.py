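"""Scoring of the standard (open-arena) T-maze / NOR / OPR battery.

The discrimination index d2 = (novel - familiar) / (novel + familiar)
quantifies object preference; animals with a strong side bias during the
familiarisation session are discarded; threshold rules classify cognitive
impairment and band T-maze performance into the clusters used for
group assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BatteryRecord",
    "d2_ratio",
    "familiarisation_filter",
    "battery_classify",
    "tmaze_bands",
]

# impairment thresholds (strict "below")
TMAZE_THRESHOLD = 0.70
NOR_D2_THRESHOLD = 0.04
OPR_D2_THRESHOLD = 0.06
FAMILIARISATION_THRESHOLD = 0.30


@dataclass
class BatteryRecord:
    mouse_id: str
    tmaze_performance: float
    nor_familiar_expl: float = float("nan")
    nor_novel_expl: float = float("nan")
    opr_familiar_expl: float = float("nan")
    opr_novel_expl: float = float("nan")
    nor_famil_pair: tuple | None = None   # familiarisation exploration (e1, e2)
    opr_famil_pair: tuple | None = None

    def __post_init__(self):
        if not 0.0 <= self.tmaze_performance <= 1.0:
            raise ValueError("tmaze_performance must lie in [0, 1]")
        for v in (self.nor_familiar_expl, self.nor_novel_expl,
                  self.opr_familiar_expl, self.opr_novel_expl):
            if not np.isnan(v) and v < 0:
                raise ValueError("exploration times must be >= 0")


def d2_ratio(novel: float, familiar: float) -> float:
    """(novel - familiar) / (novel + familiar); NaN when both are zero."""
    if novel < 0 or familiar < 0:
        raise ValueError("exploration times must be >= 0")
    total = novel + familiar
    if total == 0:
        return float("nan")
    return (novel - familiar) / total


def familiarisation_filter(e1: float, e2: float,
                           threshold: float = FAMILIARISATION_THRESHOLD
                           ) -> bool:
    """True to keep the record, False to discard.

    Discards when the normalized absolute difference |e1 - e2|/(e1 + e2)
    strictly exceeds ``threshold`` (same normalization as d2), or when
    both explorations are zero.
    """
    if e1 < 0 or e2 < 0:
        raise ValueError("exploration times must be >= 0")
    if e1 + e2 == 0:
        return False
    return abs(e1 - e2) / (e1 + e2) <= threshold


def battery_classify(record: BatteryRecord) -> dict:
    """Impairment flags from the threshold rules.

    T-maze performance below 70%, |d2(NOR)| below 0.04, |d2(OPR)| below
    0.06 flag cognitive decline; a task discarded by the familiarisation
    filter yields flag ``None`` (absent), not False.
    """
    flags: dict = {
        "tmaze_impaired": record.tmaze_performance < TMAZE_THRESHOLD}

    for task, thr in (("nor", NOR_D2_THRESHOLD), ("opr", OPR_D2_THRESHOLD)):
        pair = getattr(record, f"{task}_famil_pair")
        if pair is not None and not familiarisation_filter(*pair):
            flags[f"{task}_impaired"] = None
            continue
        novel = getattr(record, f"{task}_novel_expl")
        familiar = getattr(record, f"{task}_familiar_expl")
        if np.isnan(novel) or np.isnan(familiar):
            flags[f"{task}_impaired"] = None
            continue
        d2 = d2_ratio(novel, familiar)
        flags[f"{task}_impaired"] = (None if np.isnan(d2)
                                     else abs(d2) < thr)
    present = [v for v in flags.values() if v is not None]
    flags["any_impaired"] = any(present) if present else None
    return flags


def tmaze_bands(performance: float) -> str:
    """Performance band; 0.70 exactly falls in the 60-70% band."""
    if not 0.0 <= performance <= 1.0:
        raise ValueError("performance must lie in [0, 1]")
    if performance > 0.70:
        return ">70%"
    if performance >= 0.60:
        return "60-70%"
    if performance >= 0.50:
        return "50-60%"
    return "<50%"
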