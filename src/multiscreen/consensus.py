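"""Docking-score normalisation and ligand/structure consensus probabilities.

A MolDock-style docking score (dimensionless, more negative = better
predicted binding) is converted into a structure-based activity probability
by normalising against the best score in the table:

    prob_dc = E_lig / E_mlig        (E_mlig = the table's minimum score)

so the best-scoring compound gets exactly 1. A compound is a docking hit
when its score is strictly below the crystallographic reference ligand's.
The ligand- and structure-based probabilities are fused as

    prob_comb = (prob_dc + (1 + ESP) * p_activity) / (2 + ESP)

a convex combination whose weight on the ligand-based probability,
(1+ESP)/(2+ESP), grows with the model's average specificity ESP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem_io import LIGAND_ROW_ID, TargetConfig

__all__ = [
    "DockingEnergyTable",
    "ProbabilityRecord",
    "docking_probability",
    "docking_active",
    "combined_probability",
    "fuse",
]


@dataclass
class DockingEnergyTable:
    """Per-target docking scores plus the crystallographic-ligand reference.

    ``e_mlig`` (the best, i.e. lowest, compound score) is derived, never
    supplied; it must be negative — a table whose best pose does not bind
    carries no ranking information.
    """

    target_id: str
    entries: dict[str, float]  # compound id -> docking score
    e_inib: float  # crystallographic reference-ligand score

    def __post_init__(self) -> None:
        scores = np.array(list(self.entries.values()), dtype=float)
        if scores.size == 0:
            raise ValueError(f"{self.target_id}: docking table is empty")
        if not np.all(np.isfinite(scores)) or not np.isfinite(self.e_inib):
            raise ValueError(f"{self.target_id}: docking scores must be finite")
        if scores.min() >= 0:
            raise ValueError(
                f"{self.target_id}: best docking score must be negative"
            )

    @property
    def e_mlig(self) -> float:
        """Lowest (best) compound score in the table."""
        return float(min(self.entries.values()))

    @property
    def ligand_probability(self) -> float:
        """The reference ligand's own normalised probability."""
        return docking_probability(self.e_inib, self.e_mlig)

    @classmethod
    def from_frame(cls, target_id: str, df: pd.DataFrame) -> "DockingEnergyTable":
        """Build from a docking CSV with the reserved LIGAND_PDB reference row."""
        is_ref = df["compound_id"] == LIGAND_ROW_ID
        if is_ref.sum() != 1:
            raise ValueError(
                f"{target_id}: docking table needs exactly one {LIGAND_ROW_ID} row"
            )
        e_inib = float(df.loc[is_ref, "score"].iloc[0])
        entries = dict(
            zip(df.loc[~is_ref, "compound_id"], df.loc[~is_ref, "score"].astype(float))
        )
        return cls(target_id=target_id, entries=entries, e_inib=e_inib)


@dataclass
class ProbabilityRecord:
    """Per compound-target probabilities; absent components stay None."""

    compound_id: str
    target_id: str
    p_activity: float | None = None  # ligand-based (classifier) probability
    prob_dc: float | None = None  # structure-based (docking) probability
    prob_comb: float | None = None  # fused probability
    in_domain: bool | None = None

    def __post_init__(self) -> None:
        for name in ("p_activity", "prob_dc", "prob_comb"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")


def docking_probability(e_lig: float, e_mlig: float) -> float:
    """Normalise one docking score against the table's best score.

    Requires ``e_mlig < 0`` and ``e_mlig <= e_lig``; a non-binding pose
    (score >= 0) is clamped to probability 0 with a warning, since the sign
    flip would otherwise invert the ranking.
    """
    if not (np.isfinite(e_lig) and np.isfinite(e_mlig)):
        raise ValueError("docking scores must be finite")
    if e_mlig >= 0:
        raise ValueError(f"best table score must be negative, got {e_mlig}")
    if e_lig < e_mlig:
        raise ValueError(
            f"score {e_lig} below the table minimum {e_mlig}: inconsistent table"
        )
    if e_lig >= 0:
        if e_lig > 0:
            warnings.warn(
                f"non-binding docking score {e_lig} clamped to probability 0",
                stacklevel=2,
            )
        return 0.0
    return e_lig / e_mlig


def docking_active(e_lig: float, e_inib: float) -> bool:
    """Docking hit: binding energy strictly below the reference ligand's."""
    if not (np.isfinite(e_lig) and np.isfinite(e_inib)):
        raise ValueError("docking scores must be finite")
    return e_lig < e_inib


def combined_probability(prob_dc: float, p_activity: float, esp: float) -> float:
    """Fuse the structure- and ligand-based probabilities.

    prob_comb = (prob_dc + (1 + esp) * p_activity) / (2 + esp); a convex
    combination, so the result always lies between its two inputs.
    """
    for name, v in (("prob_dc", prob_dc), ("p_activity", p_activity), ("esp", esp)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name}={v} outside [0, 1]")
    return (prob_dc + (1.0 + esp) * p_activity) / (2.0 + esp)


def fuse(
    compound_ids: list[str],
    config: TargetConfig,
    *,
    p_activity: dict[str, float] | None = None,
    docking: DockingEnergyTable | None = None,
    in_domain: dict[str, bool] | None = None,
    esp: float | None = None,
) -> list[ProbabilityRecord]:
    """Assemble per-compound probability records for one target.

    Targets with both models get the fused ``prob_comb``; a target with only
    the classifier (no docking structure) keeps ``p_activity`` as its
    decision probability, and a docking-only target keeps ``prob_dc``.
    """
    if config.has_qsar and p_activity is None:
        raise ValueError(f"{config.target_id}: p_activity required (has_qsar)")
    if config.has_docking and docking is None:
        raise ValueError(f"{config.target_id}: docking table required (has_docking)")
    if config.mode == "combined" and esp is None:
        raise ValueError(f"{config.target_id}: esp required to fuse both models")

    records = []
    for cid in compound_ids:
        rec = ProbabilityRecord(compound_id=cid, target_id=config.target_id)
        if config.has_qsar:
            rec.p_activity = p_activity[cid]
            if in_domain is not None:
                rec.in_domain = bool(in_domain[cid])
        if config.has_docking:
            rec.prob_dc = docking_probability(docking.entries[cid], docking.e_mlig)
        if config.mode == "combined":
            rec.prob_comb = combined_probability(rec.prob_dc, rec.p_activity, esp)
        records.append(rec)
    return records
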