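"""Per-target activity calls, domain gating, and multitarget selection.

A compound is called active on a target when its decision probability passes
the target's rule and, for classifier-backed targets, the compound sits in
the model's applicability domain:

* combined targets  — prob_comb >= 0.5 AND prob_dc strictly above the
  reference ligand's probability AND in-domain;
* classifier-only   — p_activity >= 0.5 AND in-domain;
* docking-only      — prob_dc strictly above the reference ligand's.

The 0.5 threshold is inclusive; the docking comparison is strict. Compounds
active on at least ``min_targets`` targets are the multitarget hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .chem_io import TargetConfig
from .consensus import ProbabilityRecord

__all__ = [
    "TargetCall",
    "MultitargetResult",
    "call_target",
    "multitarget_count",
    "select_multitarget",
    "results_to_frame",
]

PROBABILITY_THRESHOLD = 0.5  # inclusive, per the screening rule


@dataclass(frozen=True)
class TargetCall:
    compound_id: str
    target_id: str
    decision_probability: float
    threshold: float
    in_domain: bool | None  # None for docking-only targets (no QSAR space)
    active: bool


@dataclass
class MultitargetResult:
    compound_id: str
    calls: list[TargetCall] = field(default_factory=list)

    @property
    def n_active(self) -> int:
        return sum(c.active for c in self.calls)


def call_target(
    record: ProbabilityRecord,
    config: TargetConfig,
    ligand_prob: float | None = None,
    threshold: float = PROBABILITY_THRESHOLD,
) -> TargetCall:
    """Apply one target's activity rule to a compound's probability record.

    ``ligand_prob`` is the crystallographic reference ligand's normalised
    docking probability; it is required for any docking-backed target.
    """
    if config.has_docking and ligand_prob is None:
        raise ValueError(
            f"{config.target_id}: ligand_prob required for a docking target"
        )
    mode = config.mode
    if mode == "combined":
        if record.prob_comb is None or record.prob_dc is None:
            raise ValueError(
                f"{config.target_id}: combined target needs prob_comb and prob_dc"
            )
        decision = record.prob_comb
        active = (
            decision >= threshold
            and record.prob_dc > ligand_prob
            and bool(record.in_domain)
        )
        in_dom = record.in_domain
    elif mode == "qsar_only":
        if record.p_activity is None:
            raise ValueError(f"{config.target_id}: qsar-only target needs p_activity")
        decision = record.p_activity
        active = decision >= threshold and bool(record.in_domain)
        in_dom = record.in_domain
    else:  # docking_only: the domain is defined on the QSAR space, so no gate
        if record.prob_dc is None:
            raise ValueError(f"{config.target_id}: docking-only target needs prob_dc")
        decision = record.prob_dc
        active = decision > ligand_prob
        in_dom = None
    return TargetCall(
        compound_id=record.compound_id,
        target_id=config.target_id,
        decision_probability=decision,
        threshold=threshold,
        in_domain=in_dom,
        active=bool(active),
    )


def multitarget_count(calls: list[TargetCall]) -> int:
    """Number of targets a compound is called active on (one call per target)."""
    targets = [c.target_id for c in calls]
    if len(set(targets)) != len(targets):
        dupes = sorted({t for t in targets if targets.count(t) > 1})
        raise ValueError(f"duplicate target calls: {', '.join(dupes)}")
    return sum(c.active for c in calls)


def select_multitarget(
    results: list[MultitargetResult], min_targets: int = 2
) -> list[MultitargetResult]:
    """Keep compounds active on >= min_targets targets, best-first.

    Sorted by active-target count descending, ties broken by compound id for
    deterministic reports.
    """
    if min_targets < 1:
        raise ValueError("min_targets must be >= 1")
    kept = [r for r in results if r.n_active >= min_targets]
    return sorted(kept, key=lambda r: (-r.n_active, r.compound_id))


def results_to_frame(results: list[MultitargetResult]) -> pd.DataFrame:
    """Flatten multitarget results to one row per compound.

    Columns: per-target decision probability and active flag, plus n_active —
    mirroring the study's multitarget summary table.
    """
    rows = []
    for r in results:
        row: dict[str, object] = {"compound_id": r.compound_id}
        for c in r.calls:
            row[f"{c.target_id}_prob"] = c.decision_probability
            row[f"{c.target_id}_active"] = c.active
        row["n_active"] = r.n_active
        rows.append(row)
    return pd.DataFrame(rows)
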