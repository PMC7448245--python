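"""Synthetic study generator.

Emulates the three input kinds the screening pipeline consumes, with the
statistical structure the analysis assumes, so every stage is testable
without external downloads:

* two-class descriptor matrices — actives and inactives drawn from two
  multivariate Gaussians whose means differ by a configurable number of
  pooled standard deviations along a random unit direction;
* docking-score tables — negative MolDock-style scores with a
  crystallographic reference-ligand row, actives sampled strictly below the
  reference score;
* ADMET property tables — each rule's fields sampled so its marginal pass
  probability equals a configured rate, independently across rules.

``make_full_study`` assembles a self-consistent bundle with a planted subset
of true multitarget actives, runnable end-to-end. All generators are pure
functions of (spec, seed). Generated descriptor vectors are statistical
stand-ins and do not correspond to valid molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .admet import CYP_ISOFORMS, TOX_ENDPOINTS, AdmetProfile
from .chem_io import DescriptorMatrix, LabeledDataset, TargetConfig
from .consensus import DockingEnergyTable

__all__ = [
    "DockingSim",
    "SimSpec",
    "StudyBundle",
    "make_qsar_dataset",
    "make_docking_table",
    "make_admet_table",
    "make_full_study",
]


@dataclass(frozen=True)
class DockingSim:
    """Score-generation ranges (all negative; more negative binds better)."""

    ligand_score: float = -100.0
    active_score_range: tuple[float, float] = (-180.0, -120.0)
    inactive_score_range: tuple[float, float] = (-95.0, -40.0)

    def __post_init__(self) -> None:
        for name in ("ligand_score",):
            if getattr(self, name) >= 0:
                raise ValueError("docking scores must be negative")
        for name in ("active_score_range", "inactive_score_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lower bound above upper bound")
            if hi >= 0:
                raise ValueError(f"{name}: scores must be negative")


@dataclass(frozen=True)
class SimSpec:
    """Study conditions for the synthetic generators.

    ``separation`` is the between-class mean distance in pooled-SD units;
    6 gives an easily recoverable signal, 0 a pure null. Defaults mirror the
    study scale: a few hundred training compounds per target and a screening
    library of 159 compounds.
    """

    n_active: int = 150
    n_inactive: int = 150
    n_descriptors: int = 20
    separation: float = 6.0
    noise_sd: float = 1.0
    seed: int = 1
    docking: DockingSim = DockingSim()
    admet_pass_rates: dict[str, float] = field(
        default_factory=lambda: {
            "solubility": 0.66,
            "absorption": 0.8,
            "bbb": 0.3,
            "toxicity": 0.5,
        }
    )
    n_library: int = 159
    n_planted: int = 40

    def __post_init__(self) -> None:
        if min(self.n_active, self.n_inactive) < 1:
            raise ValueError("class counts must be >= 1")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for rule, rate in self.admet_pass_rates.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"pass rate for {rule} outside [0, 1]")
        if not 0 <= self.n_planted <= self.n_library:
            raise ValueError("n_planted must lie in [0, n_library]")


def _class_means(spec: SimSpec, rng: np.random.Generator) -> np.ndarray:
    """A random unit direction scaled so the means differ by
    ``separation`` pooled SDs."""
    direction = rng.normal(size=spec.n_descriptors)
    direction /= np.linalg.norm(direction)
    return direction * spec.separation * spec.noise_sd


def make_qsar_dataset(
    spec: SimSpec, target: TargetConfig | None = None
) -> LabeledDataset:
    """Two-Gaussian labelled descriptor dataset, deterministic per seed."""
    if target is None:
        target = TargetConfig("SYN", activity_threshold=6.0)
    rng = np.random.default_rng(spec.seed)
    delta = _class_means(spec, rng)
    X_act = rng.normal(delta, spec.noise_sd, (spec.n_active, spec.n_descriptors))
    X_inact = rng.normal(0.0, spec.noise_sd, (spec.n_inactive, spec.n_descriptors))
    X = np.vstack([X_act, X_inact])
    y = np.concatenate(
        [np.ones(spec.n_active, dtype=int), np.zeros(spec.n_inactive, dtype=int)]
    )
    ids = [f"C{i + 1:04d}" for i in range(len(y))]
    names = [f"d{j + 1:02d}" for j in range(spec.n_descriptors)]
    return LabeledDataset(
        target=target,
        X=DescriptorMatrix(compound_ids=ids, descriptor_names=names, values=X),
        y=y,
    )


def make_docking_table(
    spec: SimSpec,
    compound_ids: list[str],
    active_mask: np.ndarray,
    target_id: str = "SYN",
    rng: np.random.Generator | None = None,
) -> DockingEnergyTable:
    """Docking-score table: actives below the reference ligand, decoys above.

    When any compound is marked active the active score range must lie
    strictly below the reference-ligand score, so planted actives are
    docking hits by construction.
    """
    active_mask = np.asarray(active_mask, dtype=bool)
    if len(active_mask) != len(compound_ids):
        raise ValueError("active_mask length must match compound_ids")
    d = spec.docking
    if active_mask.any() and d.active_score_range[1] >= d.ligand_score:
        raise ValueError(
            "active score range must lie strictly below the ligand score"
        )
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    scores = np.where(
        active_mask,
        rng.uniform(*d.active_score_range, len(compound_ids)),
        rng.uniform(*d.inactive_score_range, len(compound_ids)),
    )
    return DockingEnergyTable(
        target_id=target_id,
        entries=dict(zip(compound_ids, scores.astype(float))),
        e_inib=d.ligand_score,
    )


def make_admet_table(
    spec: SimSpec,
    compound_ids: list[str],
    rng: np.random.Generator | None = None,
) -> list[AdmetProfile]:
    """ADMET profiles with configured marginal pass rates, independent per rule."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    rates = spec.admet_pass_rates
    profiles = []
    for cid in compound_ids:
        sol_pass = rng.random() < rates.get("solubility", 1.0)
        abs_pass = rng.random() < rates.get("absorption", 1.0)
        bbb_pass = rng.random() < rates.get("bbb", 1.0)
        tox_pass = rng.random() < rates.get("toxicity", 1.0)
        rot_pass = rng.random() < rates.get("rotatable", 1.0)

        if abs_pass:
            mw = rng.uniform(250, 450)
            logp = rng.uniform(0.5, 4.0)
            hbd, hba = int(rng.integers(0, 6)), int(rng.integers(0, 11))
            pgp = False
        else:
            # consensus logP above the 4.15 cap guarantees the stage fails
            mw = rng.uniform(450, 700)
            logp = rng.uniform(4.3, 8.0)
            hbd, hba = int(rng.integers(0, 9)), int(rng.integers(0, 14))
            pgp = bool(rng.random() < 0.5)
        tox = {ep: "none" for ep in TOX_ENDPOINTS}
        if not tox_pass:
            ep = TOX_ENDPOINTS[int(rng.integers(len(TOX_ENDPOINTS)))]
            tox[ep] = "low" if rng.random() < 0.5 else "high"
        profiles.append(
            AdmetProfile(
                compound_id=cid,
                mw=float(mw),
                consensus_logp=float(logp),
                hbd=hbd,
                hba=hba,
                rotatable_bonds=int(
                    rng.integers(0, 11) if rot_pass else rng.integers(11, 21)
                ),
                solubility_class=(
                    ("soluble", "moderately_soluble")[int(rng.integers(2))]
                    if sol_pass
                    else ("poorly_soluble", "insoluble")[int(rng.integers(2))]
                ),
                pgp_substrate=pgp,
                bbb_permeant=bool(bbb_pass),
                cyp_inhibition={
                    iso: bool(rng.random() < 0.3) for iso in CYP_ISOFORMS
                },
                tox=tox,
            )
        )
    return profiles


def admet_profiles_to_frame(profiles: list[AdmetProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row: dict[str, object] = {
            "compound_id": p.compound_id,
            "mw": p.mw,
            "consensus_logp": p.consensus_logp,
            "hbd": p.hbd,
            "hba": p.hba,
            "rotatable_bonds": p.rotatable_bonds,
            "solubility_class": p.solubility_class,
            "pgp_substrate": p.pgp_substrate,
            "bbb_permeant": p.bbb_permeant,
        }
        row.update({f"cyp_{k}": v for k, v in p.cyp_inhibition.items()})
        row.update({f"tox_{k}": v for k, v in p.tox.items()})
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class StudyBundle:
    """A self-consistent synthetic study, runnable end-to-end.

    Each target has its own descriptor space; planted library compounds are
    drawn from every target's active-class Gaussian (and score as docking
    hits on every docking target), so they are true multitarget actives.
    """

    spec: SimSpec
    targets: dict[str, TargetConfig]
    train_datasets: dict[str, LabeledDataset]  # per QSAR-capable target
    library_ids: list[str]
    library_X: dict[str, DescriptorMatrix]  # per QSAR-capable target
    docking_tables: dict[str, DockingEnergyTable]  # per docking-capable target
    admet_profiles: list[AdmetProfile]
    planted_ids: set[str]


def make_full_study(
    spec: SimSpec, targets: dict[str, TargetConfig]
) -> StudyBundle:
    """Generate training sets, library descriptors, docking and ADMET tables.

    Seeds for every component are derived from ``spec.seed`` through a
    NumPy ``SeedSequence``, so the whole bundle is a pure function of the
    spec.
    """
    if not targets:
        raise ValueError("at least one target required")
    root = np.random.SeedSequence(spec.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ["library", "admet", *sorted(targets)],
            root.spawn(2 + len(targets)),
        )
    }

    lib_rng = streams["library"]
    library_ids = [f"L{i + 1:04d}" for i in range(spec.n_library)]
    planted_idx = lib_rng.choice(spec.n_library, size=spec.n_planted, replace=False)
    planted_mask = np.zeros(spec.n_library, dtype=bool)
    planted_mask[planted_idx] = True
    planted_ids = {library_ids[i] for i in np.flatnonzero(planted_mask)}

    train_datasets: dict[str, LabeledDataset] = {}
    library_X: dict[str, DescriptorMatrix] = {}
    docking_tables: dict[str, DockingEnergyTable] = {}
    names = [f"d{j + 1:02d}" for j in range(spec.n_descriptors)]

    for tid in sorted(targets):
        cfg = targets[tid]
        rng = streams[tid]
        if cfg.has_qsar:
            delta = _class_means(spec, rng)
            X_act = rng.normal(
                delta, spec.noise_sd, (spec.n_active, spec.n_descriptors)
            )
            X_inact = rng.normal(
                0.0, spec.noise_sd, (spec.n_inactive, spec.n_descriptors)
            )
            y = np.concatenate(
                [
                    np.ones(spec.n_active, dtype=int),
                    np.zeros(spec.n_inactive, dtype=int),
                ]
            )
            ids = [f"{tid}-T{i + 1:04d}" for i in range(len(y))]
            train_datasets[tid] = LabeledDataset(
                target=cfg,
                X=DescriptorMatrix(ids, names, np.vstack([X_act, X_inact])),
                y=y,
            )
            # library compounds live in the same per-target descriptor space
            lib_vals = np.where(
                planted_mask[:, None],
                rng.normal(delta, spec.noise_sd, (spec.n_library, spec.n_descriptors)),
                rng.normal(0.0, spec.noise_sd, (spec.n_library, spec.n_descriptors)),
            )
            library_X[tid] = DescriptorMatrix(list(library_ids), names, lib_vals)
        if cfg.has_docking:
            docking_tables[tid] = make_docking_table(
                spec, library_ids, planted_mask, target_id=tid, rng=rng
            )

    admet_profiles = make_admet_table(spec, library_ids, rng=streams["admet"])
    return StudyBundle(
        spec=spec,
        targets=dict(targets),
        train_datasets=train_datasets,
        library_ids=library_ids,
        library_X=library_X,
        docking_tables=docking_tables,
        admet_profiles=admet_profiles,
        planted_ids=planted_ids,
    )
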