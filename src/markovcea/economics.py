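"""Incremental cost-effectiveness arithmetic: ICER, dominance, NMB, decisions.

Conventions: strategy ``a`` is the intervention, ``b`` the comparator; deltas
are ``a - b``.  An ICER is only meaningful when the incremental QALYs are
nonzero and the pair is not in a dominance quadrant; otherwise the result
carries an explicit tag rather than a signed number or infinity.  Decisions at
a willingness-to-pay (WTP) threshold follow the net-monetary-benefit rule
``NMB = WTP * QALY - cost`` with strict inequality, which coincides with the
``ICER < WTP`` rule whenever incremental QALYs are positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .survival import ValidationError

__all__ = [
    "DEFAULT_WTP",
    "CEResult",
    "compute_icer",
    "net_monetary_benefit",
]

#: 3x 2020 Chinese GDP per capita, USD/QALY.
DEFAULT_WTP = 31451.64


@dataclass(frozen=True)
class CEResult:
    """Pairwise cost-effectiveness comparison (intervention vs comparator)."""

    cost_intervention: float
    qaly_intervention: float
    cost_comparator: float
    qaly_comparator: float
    delta_cost: float
    delta_qaly: float
    icer: Optional[float]        # None when tagged (dominance / equal effectiveness)
    icer_tag: Optional[str]      # "dominant" | "dominated" | "equal_effectiveness" | None
    quadrant: str                # CE-plane quadrant of (delta_qaly, delta_cost)
    wtp_threshold: float
    decision: str                # "cost_effective" | "not_cost_effective" | "dominant" | "dominated"

    def to_dict(self) -> dict:
        return {
            "intervention": {"cost": self.cost_intervention, "qaly": self.qaly_intervention},
            "comparator": {"cost": self.cost_comparator, "qaly": self.qaly_comparator},
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "icer_tag": self.icer_tag,
            "quadrant": self.quadrant,
            "wtp_threshold": self.wtp_threshold,
            "decision": self.decision,
        }


def _quadrant(dq: float, dc: float) -> str:
    # NE: more effective & costlier; SE: more effective & cheaper (dominant);
    # NW: less effective & costlier (dominated); SW: less effective & cheaper.
    if dq > 0:
        return "NE" if dc >= 0 else "SE"
    if dq < 0:
        return "NW" if dc >= 0 else "SW"
    return "axis"


def compute_icer(
    cost_a: float,
    qaly_a: float,
    cost_b: float,
    qaly_b: float,
    wtp: float = DEFAULT_WTP,
) -> CEResult:
    """Pairwise incremental comparison of intervention ``a`` vs comparator ``b``."""
    for name, v in (("cost_a", cost_a), ("qaly_a", qaly_a), ("cost_b", cost_b), ("qaly_b", qaly_b)):
        if not math.isfinite(v):
            raise ValidationError(f"{name}: must be finite, got {v}")
    if wtp < 0:
        raise ValidationError(f"wtp: threshold must be non-negative, got {wtp}")

    dc, dq = cost_a - cost_b, qaly_a - qaly_b
    icer: Optional[float] = None
    tag: Optional[str] = None
    if dc < 0 and dq > 0:
        tag = "dominant"
    elif dc > 0 and dq < 0:
        tag = "dominated"
    elif dq == 0:
        tag = "equal_effectiveness"
    else:
        icer = dc / dq

    if tag == "dominant":
        decision = "dominant"
    elif tag == "dominated":
        decision = "dominated"
    else:
        nmb_gain = wtp * dq - dc
        decision = "cost_effective" if nmb_gain > 0 else "not_cost_effective"

    return CEResult(
        cost_intervention=cost_a,
        qaly_intervention=qaly_a,
        cost_comparator=cost_b,
        qaly_comparator=qaly_b,
        delta_cost=dc,
        delta_qaly=dq,
        icer=icer,
        icer_tag=tag,
        quadrant=_quadrant(dq, dc),
        wtp_threshold=wtp,
        decision=decision,
    )


def net_monetary_benefit(cost: float, qaly: float, wtp: float) -> float:
    """``wtp * qaly - cost`` in USD."""
    if wtp < 0:
        raise ValidationError(f"wtp: threshold must be non-negative, got {wtp}")
    return wtp * qaly - cost
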