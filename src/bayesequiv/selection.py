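"""Equivalence-region selection from objective error-rate criteria.

Given a table of Monte-Carlo error rates (from :mod:`.simulation`) and a
set of desiderata -- a maximum tolerable type I error rate, a minimum
power against a stated effect size, the attainable per-group sample size
and an elicited prior -- this module ranks the candidate (method,
equivalence region) pairs and recommends the narrowest admissible
region.  A narrower region makes the resulting equivalence statement
more precise, so width is the primary ranking key; the type I error rate
breaks ties, then power.

The prior is an input, never a tuning knob: a selection call operates on
a single prior scale, and requests spanning several scales are refused.
A variant ranks by the total misclassification rate (type I + type II),
which implicitly assumes equal losses for the two error kinds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidDataError, MissingCellsError
from .simulation import ErrorRateRecord, records_to_frame

__all__ = [
    "SelectionCriteria",
    "SelectionEntry",
    "Recommendation",
    "select_design",
    "select_by_total_error",
]


@dataclass(frozen=True)
class SelectionCriteria:
    """Desiderata for choosing a test method and equivalence region."""

    alpha_max: float
    power_min: float
    n: int
    prior_scale: float
    effect_label: str = "small"
    methods: tuple | None = None  # default: every method in the table
    regions: tuple | None = None  # (lower, upper) pairs; default: all in table
    conservative: bool = False  # require alpha + 2 SE and power - 2 SE to pass

    def __post_init__(self):
        if not 0 < self.alpha_max < 1:
            raise InvalidDataError("alpha_max must lie in (0, 1)")
        if not 0 < self.power_min < 1:
            raise InvalidDataError("power_min must lie in (0, 1)")
        if self.n < 2:
            raise InvalidDataError("n must be >= 2")


@dataclass(frozen=True)
class SelectionEntry:
    method: str
    region_lower: float
    region_upper: float
    alpha: float
    alpha_se: float
    power: float
    power_se: float
    total_error: float
    admissible: bool

    @property
    def width(self) -> float:
        return self.region_upper - self.region_lower


@dataclass(frozen=True)
class Recommendation:
    """Ranked candidate list with the chosen entry (or none)."""

    entries: tuple
    chosen: SelectionEntry | None
    n_used: int
    criteria: SelectionCriteria
    mode: str  # "error_rates" | "total_error"
    diagnostics: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "rank": i + 1, "method": e.method,
            "region_lower": e.region_lower, "region_upper": e.region_upper,
            "alpha": e.alpha, "alpha_se": e.alpha_se,
            "power": e.power, "power_se": e.power_se,
            "total_error": e.total_error, "admissible": e.admissible,
        } for i, e in enumerate(self.entries)]
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = [
            f"Selection at n={self.n_used} (requested {self.criteria.n}), "
            f"prior scale {self.criteria.prior_scale:g}, "
            f"effect '{self.criteria.effect_label}', mode {self.mode}",
        ]
        if self.mode == "error_rates":
            lines.append(f"criteria: alpha <= {self.criteria.alpha_max:g}, "
                         f"power >= {self.criteria.power_min:g}")
        if self.chosen is None:
            lines.append("chosen: none (no admissible method/region pair)")
            if self.diagnostics:
                lines.append(f"nearest miss: {self.diagnostics}")
        else:
            c = self.chosen
            lines.append(
                f"chosen: {c.method} with region [{c.region_lower:g}, "
                f"{c.region_upper:g}] (alpha={c.alpha:.4f}, power={c.power:.4f})"
            )
        for i, e in enumerate(self.entries):
            flag = "ok " if e.admissible else "-- "
            lines.append(
                f"  {i + 1:2d}. {flag}{e.method:<12s} [{e.region_lower:+.3f}, "
                f"{e.region_upper:+.3f}]  alpha={e.alpha:.4f}  "
                f"power={e.power:.4f}  total={e.total_error:.4f}"
            )
        return "\n".join(lines)


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    if isinstance(table, (list, tuple)) and (not table or isinstance(table[0], ErrorRateRecord)):
        return records_to_frame(list(table))
    raise InvalidDataError("table must be a results DataFrame or list of records")


def _gather(table, criteria: SelectionCriteria):
    """Pair up the null-setting and effect-setting cells per candidate."""
    df = _as_frame(table)
    scales = sorted(df["prior_scale"].unique())
    sel = df[np.isclose(df["prior_scale"], criteria.prior_scale)]
    if sel.empty:
        raise MissingCellsError(
            f"no cells at prior scale {criteria.prior_scale:g} "
            f"(table has scales {scales})")
    need = sel[sel["setting"].isin(["null", criteria.effect_label])]
    n_avail = sorted(need["n"].unique())
    candidates = [n for n in n_avail if n <= criteria.n]
    if not candidates:
        raise MissingCellsError(
            f"no simulated n at or below {criteria.n} (available: {n_avail})")
    n_used = max(candidates)
    need = need[need["n"] == n_used]

    methods = tuple(criteria.methods) if criteria.methods else \
        tuple(sorted(need["method"].unique()))
    if criteria.regions:
        regions = tuple((float(lo), float(hi)) for lo, hi in criteria.regions)
    else:
        regions = tuple(sorted(
            {(float(lo), float(hi))
             for lo, hi in zip(need["region_lower"], need["region_upper"])}))

    entries, missing = [], []
    for method in methods:
        for lo, hi in regions:
            cell = need[(need["method"] == method)
                        & np.isclose(need["region_lower"], lo)
                        & np.isclose(need["region_upper"], hi)]
            null_cell = cell[cell["setting"] == "null"]
            eff_cell = cell[cell["setting"] == criteria.effect_label]
            if null_cell.empty or eff_cell.empty:
                for lbl, c in (("null", null_cell), (criteria.effect_label, eff_cell)):
                    if c.empty:
                        missing.append({"setting": lbl, "method": method,
                                        "region": (lo, hi), "n": n_used,
                                        "prior_scale": criteria.prior_scale})
                continue
            nr, er = null_cell.iloc[0], eff_cell.iloc[0]
            entries.append({
                "method": method, "lo": lo, "hi": hi,
                "alpha": float(nr["type1"]), "alpha_se": float(nr["type1_se"]),
                "power": float(er["power"]), "power_se": float(er["power_se"]),
                "beta": 1.0 - float(er["power"]),
            })
    if missing:
        raise MissingCellsError(
            f"{len(missing)} required simulation cell(s) are missing from the "
            f"table; run them first", missing=missing)
    return entries, n_used


def _build(entries, admissible_fn, criteria, n_used, mode) -> Recommendation:
    built = []
    for e in entries:
        built.append(SelectionEntry(
            method=e["method"], region_lower=e["lo"], region_upper=e["hi"],
            alpha=e["alpha"], alpha_se=e["alpha_se"],
            power=e["power"], power_se=e["power_se"],
            total_error=e["alpha"] + e["beta"],
            admissible=admissible_fn(e),
        ))
    built.sort(key=lambda x: (not x.admissible, x.width, x.alpha, -x.power,
                              x.method))
    chosen = built[0] if built and built[0].admissible else None
    diagnostics = ""
    if chosen is None and built:
        near = min(built, key=lambda x: (max(0.0, x.alpha - criteria.alpha_max)
                                         + max(0.0, criteria.power_min - x.power)))
        diagnostics = (f"{near.method} [{near.region_lower:g}, "
                       f"{near.region_upper:g}] with alpha={near.alpha:.4f}, "
                       f"power={near.power:.4f}")
    return Recommendation(entries=tuple(built), chosen=chosen, n_used=n_used,
                          criteria=criteria, mode=mode, diagnostics=diagnostics)


def select_design(table, criteria: SelectionCriteria) -> Recommendation:
    """Recommend the narrowest admissible (method, region) pair.

    Admissible means the estimated type I error (null setting) is at most
    ``alpha_max`` and the estimated power (effect setting) is at least
    ``power_min``, both read at the largest simulated n not exceeding
    ``criteria.n``.  With ``conservative=True`` a two-SE margin is
    required on both.  A pure function of the table and criteria.
    """
    entries, n_used = _gather(table, criteria)

    tol = 1e-12  # guard float noise at exact criterion boundaries
    if criteria.conservative:
        def ok(e):
            return (e["alpha"] + 2 * e["alpha_se"] <= criteria.alpha_max + tol
                    and e["power"] - 2 * e["power_se"] >= criteria.power_min - tol)
    else:
        def ok(e):
            return (e["alpha"] <= criteria.alpha_max + tol
                    and e["power"] >= criteria.power_min - tol)
    return _build(entries, ok, criteria, n_used, "error_rates")


def select_by_total_error(table, criteria: SelectionCriteria,
                          total_max: float) -> Recommendation:
    """Variant admitting pairs whose total error (type I + type II) is small.

    ``total_max`` bounds the sum of the type I rate under the null setting
    and the non-detection rate 1 - power under the effect setting (an
    inconclusive result counts as a failure to detect).  This treats both
    error kinds as equally costly, which should be kept in mind when the
    losses differ (a false positive and a false negative rarely cost the
    same in biomedical practice).
    """
    if not 0 <= total_max <= 1:
        raise InvalidDataError("total_max must lie in [0, 1]")
    entries, n_used = _gather(table, criteria)

    tol = 1e-12
    def ok(e):
        if criteria.conservative:
            return (e["alpha"] + e["beta"]
                    + 2 * np.hypot(e["alpha_se"], e["power_se"]) <= total_max + tol)
        return e["alpha"] + e["beta"] <= total_max + tol
    return _build(entries, ok, criteria, n_used, "total_error")
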