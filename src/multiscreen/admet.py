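"""Rule-based ADMET funnel over precomputed property tables.

Property predictions (physicochemical values, solubility class, P-gp,
blood-brain-barrier permeation, CYP flags, toxicity risk levels) come from
external predictors as CSV; this module applies the conjunctive drug-likeness
rules: at most two Lipinski violations, consensus logP <= 4.15, no P-gp
efflux, acceptable solubility, BBB permeation for CNS candidates, and no
predicted toxicity risk on any of the four endpoints. CYP flags are carried
through and reported but never filtered on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "AdmetProfile",
    "FunnelStage",
    "FunnelReport",
    "lipinski_violations",
    "absorption_filter",
    "toxicity_filter",
    "admet_funnel",
    "profiles_from_frame",
    "DEFAULT_STAGES",
]

SOLUBILITY_CLASSES = {"soluble", "moderately_soluble", "poorly_soluble", "insoluble"}
TOX_LEVELS = {"none", "low", "high"}
TOX_ENDPOINTS = ("mutagenic", "tumorigenic", "reproductive", "irritant")
CYP_ISOFORMS = ("CYP1A2", "CYP2C19", "CYP2C9", "CYP2D6", "CYP3A4")
LOGP_CONSENSUS_CAP = 4.15
MAX_LIPINSKI_VIOLATIONS = 2


@dataclass
class AdmetProfile:
    compound_id: str
    mw: float  # molecular weight, Da
    consensus_logp: float
    hbd: int  # hydrogen-bond donors
    hba: int  # hydrogen-bond acceptors
    rotatable_bonds: int
    solubility_class: str
    pgp_substrate: bool
    bbb_permeant: bool
    cyp_inhibition: dict[str, bool] = field(default_factory=dict)
    tox: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError(f"{self.compound_id}: mw must be positive")
        if min(self.hbd, self.hba, self.rotatable_bonds) < 0:
            raise ValueError(f"{self.compound_id}: counts must be non-negative")
        if self.solubility_class not in SOLUBILITY_CLASSES:
            raise ValueError(
                f"{self.compound_id}: unknown solubility class "
                f"{self.solubility_class!r}"
            )
        for endpoint, level in self.tox.items():
            if level not in TOX_LEVELS:
                raise ValueError(
                    f"{self.compound_id}: unknown toxicity level {level!r} "
                    f"for {endpoint}"
                )


def lipinski_violations(profile: AdmetProfile) -> int:
    """Count rule-of-five violations (0-4), boundaries on the compliant side.

    Rules: MW <= 500 Da, logP <= 5, H-bond donors <= 5, H-bond acceptors <= 10.
    """
    for name in ("mw", "consensus_logp", "hbd", "hba"):
        if getattr(profile, name) is None:
            raise ValueError(f"{profile.compound_id}: missing field {name}")
    return sum(
        [
            profile.mw > 500,
            profile.consensus_logp > 5,
            profile.hbd > 5,
            profile.hba > 10,
        ]
    )


def absorption_filter(profile: AdmetProfile) -> bool:
    """Good absorption: <= 2 Lipinski violations, consensus logP <= 4.15,
    and not a P-glycoprotein efflux substrate. Boundaries inclusive."""
    return (
        lipinski_violations(profile) <= MAX_LIPINSKI_VIOLATIONS
        and profile.consensus_logp <= LOGP_CONSENSUS_CAP
        and not profile.pgp_substrate
    )


def solubility_filter(profile: AdmetProfile) -> bool:
    """Acceptable solubility: soluble or moderately soluble."""
    return profile.solubility_class in {"soluble", "moderately_soluble"}


def bbb_filter(profile: AdmetProfile) -> bool:
    """Predicted to cross the blood-brain barrier (needed for CNS targets)."""
    return profile.bbb_permeant


def veber_filter(profile: AdmetProfile) -> bool:
    """Optional extra stage: <= 10 rotatable bonds (Veber's rule)."""
    return profile.rotatable_bonds <= 10


def toxicity_filter(profile: AdmetProfile) -> bool:
    """No predicted risk: every toxicity endpoint at level 'none'.

    Any non-'none' level (including 'low') counts as a risk and fails.
    """
    for endpoint in TOX_ENDPOINTS:
        if endpoint not in profile.tox:
            raise ValueError(
                f"{profile.compound_id}: missing toxicity endpoint {endpoint}"
            )
        level = profile.tox[endpoint]
        if level not in TOX_LEVELS:
            raise ValueError(
                f"{profile.compound_id}: unknown toxicity level {level!r}"
            )
        if level != "none":
            return False
    return True


_STAGE_RULES = {
    "solubility": solubility_filter,
    "absorption": absorption_filter,
    "bbb": bbb_filter,
    "rotatable": veber_filter,
    "toxicity": toxicity_filter,
}

#: The standard funnel order: solubility, then absorption (Lipinski/logP/P-gp),
#: then blood-brain barrier, then toxicity.
DEFAULT_STAGES = ("solubility", "absorption", "bbb", "toxicity")


@dataclass
class FunnelStage:
    name: str
    n_in: int
    n_out: int
    survivors: list[str]


@dataclass
class FunnelReport:
    stages: list[FunnelStage]

    @property
    def final_survivors(self) -> list[str]:
        return self.stages[-1].survivors if self.stages else []

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.name, s.n_in, s.n_out) for s in self.stages],
            columns=["stage", "n_in", "n_out"],
        )


def admet_funnel(
    profiles: list[AdmetProfile],
    stages: tuple[str, ...] = DEFAULT_STAGES,
) -> FunnelReport:
    """Run profiles through the ordered rule funnel.

    Each stage keeps only the survivors of the previous one; because the
    rules are conjunctive, the final set does not depend on the stage order
    (the per-stage counts do). Unknown stage names raise ``ValueError``.
    """
    for name in stages:
        if name not in _STAGE_RULES:
            raise ValueError(
                f"unknown funnel stage {name!r}; known: {sorted(_STAGE_RULES)}"
            )
    current = list(profiles)
    report = FunnelReport(stages=[])
    for name in stages:
        rule = _STAGE_RULES[name]
        survivors = [p for p in current if rule(p)]
        report.stages.append(
            FunnelStage(
                name=name,
                n_in=len(current),
                n_out=len(survivors),
                survivors=[p.compound_id for p in survivors],
            )
        )
        current = survivors
    return report


def profiles_from_frame(df: pd.DataFrame) -> list[AdmetProfile]:
    """Build profiles from an ADMET CSV (``tox_*`` and ``cyp_*`` column groups)."""
    profiles = []
    for _, row in df.iterrows():
        profiles.append(
            AdmetProfile(
                compound_id=str(row["compound_id"]),
                mw=float(row["mw"]),
                consensus_logp=float(row["consensus_logp"]),
                hbd=int(row["hbd"]),
                hba=int(row["hba"]),
                rotatable_bonds=int(row["rotatable_bonds"]),
                solubility_class=str(row["solubility_class"]),
                pgp_substrate=bool(row["pgp_substrate"]),
                bbb_permeant=bool(row["bbb_permeant"]),
                cyp_inhibition={
                    iso: bool(row[f"cyp_{iso}"])
                    for iso in CYP_ISOFORMS
                    if f"cyp_{iso}" in df.columns
                },
                tox={
                    ep: str(row[f"tox_{ep}"])
                    for ep in TOX_ENDPOINTS
                    if f"tox_{ep}" in df.columns
                },
            )
        )
    return profiles
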