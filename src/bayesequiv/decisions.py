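"""Three-way equivalence decisions and their Monte-Carlo classification.

Every test in the package maps its evidence (a Bayes factor BF01 or an
interval estimate relative to an equivalence region) to one of three
outcomes: ``accept_H0`` (equivalence established), ``reject_H0``
(non-equivalence) or ``inconclusive`` (more data needed).
"""

from __future__ import annotations

from dataclasses import dataclass

from .bayes_factors import BFResult
from .core import EquivalenceRegion
from .errors import InvalidDataError, ScaleMismatchError
from .posterior import IntervalEstimate

__all__ = [
    "ACCEPT_H0", "REJECT_H0", "INCONCLUSIVE",
    "Decision", "bf_decision", "rope_decision", "classify_outcome",
    "BF_METHODS", "ROPE_METHODS", "ALL_METHODS",
]

ACCEPT_H0 = "accept_H0"
REJECT_H0 = "reject_H0"
INCONCLUSIVE = "inconclusive"

BF_METHODS = ("jzs_bf", "oh_bf", "noh_bf", "hybrid_bf")
ROPE_METHODS = ("rope_hpd95", "rope_full", "rope_support")
ALL_METHODS = BF_METHODS + ROPE_METHODS


@dataclass(frozen=True)
class Decision:
    outcome: str  # one of ACCEPT_H0 / REJECT_H0 / INCONCLUSIVE
    method: str   # one of ALL_METHODS
    evidence: tuple  # (bf01,) or (interval lower, interval upper), for audit

    def __post_init__(self):
        if self.outcome not in (ACCEPT_H0, REJECT_H0, INCONCLUSIVE):
            raise InvalidDataError(f"unknown outcome {self.outcome!r}")


def bf_decision(bf: BFResult, threshold: float = 3.0, method: str | None = None) -> Decision:
    """Map a Bayes factor to a three-way decision at an evidence threshold.

    BF01 >= threshold accepts the (interval) null, BF01 <= 1/threshold
    rejects it, anything in between is inconclusive.  The default
    threshold of 3 demands at least moderate evidence either way.
    Boundary values count toward the decisive side, fixed for determinism.
    """
    if not threshold > 1:
        raise InvalidDataError("threshold must be > 1")
    if method is None:
        method = bf.model.model + "_bf"
    if bf.bf01 <= 1 / threshold:
        outcome = REJECT_H0
    elif bf.bf01 >= threshold:
        outcome = ACCEPT_H0
    else:
        outcome = INCONCLUSIVE
    return Decision(outcome=outcome, method=method, evidence=(bf.bf01,))


def rope_decision(interval: IntervalEstimate, region: EquivalenceRegion,
                  method: str | None = None) -> Decision:
    """Locate an interval estimate relative to an equivalence region.

    Containment is closed (an endpoint exactly on the region boundary
    counts as inside); rejection requires strict separation.  An empty
    support interval is inconclusive: an empty set would vacuously lie
    inside any region, which would be an absurd acceptance.
    """
    if region.scale != "standardized_effect":
        raise ScaleMismatchError("ROPE decisions operate on the delta scale")
    if method is None:
        method = {"hpd95": "rope_hpd95", "hpd100": "rope_full",
                  "support": "rope_support"}.get(interval.kind, "rope_hpd95")
    if interval.is_empty:
        outcome = INCONCLUSIVE
    elif region.lower <= interval.lower and interval.upper <= region.upper:
        outcome = ACCEPT_H0
    elif interval.upper < region.lower or interval.lower > region.upper:
        outcome = REJECT_H0
    else:
        outcome = INCONCLUSIVE
    return Decision(outcome=outcome, method=method,
                    evidence=(interval.lower, interval.upper))


def classify_outcome(d: Decision, truth: str) -> str:
    """Classify a decision against the known truth of a simulation cell.

    ``truth`` is "null_true" (true delta inside the practically-equivalent
    range) or "effect_present".  Rejecting under a true null is a type I
    error; accepting under a present effect is a type II error; rejecting
    under a present effect counts toward power; inconclusive results
    contribute to no error rate.
    """
    if truth not in ("null_true", "effect_present"):
        raise InvalidDataError(f"unknown truth {truth!r}")
    if d.outcome == INCONCLUSIVE:
        return "inconclusive"
    if truth == "null_true":
        return "type_I" if d.outcome == REJECT_H0 else "correct_acceptance"
    return "correct_detection" if d.outcome == REJECT_H0 else "type_II"
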