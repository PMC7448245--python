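"""End-to-end orchestration: train, gate, fuse, screen, filter, report.

The stages run in the study order — per-target QSAR models with
applicability domains, docking-score normalisation, consensus fusion,
multitarget selection, then the ADMET funnel — behind a single declarative
``RunConfig``. Every run writes CSV outputs plus a JSON manifest recording
the config hash and seed, and re-running with identical inputs and config
reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import admet as admet_mod
from .applicability import fit_apd, in_domain
from .chem_io import (
    DEFAULT_TARGETS,
    LIGAND_ROW_ID,
    DescriptorMatrix,
    LabeledDataset,
    TargetConfig,
    read_table,
)
from .consensus import DockingEnergyTable, fuse
from .qsar import (
    ForestSpec,
    SplitSpec,
    cross_validate,
    model_esp,
    predict_activity_probability,
    stratified_split,
    train_forest,
    validate_on_test,
)
from .screening import (
    MultitargetResult,
    call_target,
    results_to_frame,
    select_multitarget,
)
from .synthdata import StudyBundle, admet_profiles_to_frame

__all__ = ["RunConfig", "StudyResult", "validate_config", "run_study", "run_all",
           "write_bundle", "read_bundle"]

log = logging.getLogger("multiscreen")


@dataclass
class RunConfig:
    targets: dict[str, TargetConfig] = field(
        default_factory=lambda: dict(DEFAULT_TARGETS)
    )
    split: SplitSpec = SplitSpec()
    forest: ForestSpec = ForestSpec()
    apd_z: float = 0.5
    cv_folds: int = 10
    probability_threshold: float = 0.5
    min_targets: int = 2
    admet_stages: tuple[str, ...] = admet_mod.DEFAULT_STAGES
    input_dir: str | None = None
    output_dir: str | None = None
    seed: int = 1

    def config_hash(self) -> str:
        payload = {
            "targets": {
                t: asdict(c) for t, c in sorted(self.targets.items())
            },
            "split": asdict(self.split),
            "forest": asdict(self.forest),
            "apd_z": self.apd_z,
            "cv_folds": self.cv_folds,
            "probability_threshold": self.probability_threshold,
            "min_targets": self.min_targets,
            "admet_stages": list(self.admet_stages),
            "seed": self.seed,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of violations (empty = ok), each naming field and constraint."""
    violations = []
    if not 0 < config.split.train_fraction < 1:
        violations.append("split.train_fraction: must be in (0, 1)")
    if config.forest.n_trees < 1:
        violations.append("forest.n_trees: must be >= 1")
    if config.cv_folds < 2:
        violations.append("cv_folds: must be >= 2")
    if not 0 <= config.probability_threshold <= 1:
        violations.append("probability_threshold: must be in [0, 1]")
    if config.min_targets < 1:
        violations.append("min_targets: must be >= 1")
    for name in config.admet_stages:
        if name not in admet_mod._STAGE_RULES:
            violations.append(f"admet_stages: unknown stage {name!r}")
    for tid, cfg in config.targets.items():
        if not (cfg.has_qsar or cfg.has_docking):
            violations.append(
                f"targets.{tid}: at least one of has_qsar/has_docking required"
            )
    return violations


@dataclass
class StudyResult:
    performance: pd.DataFrame  # per target x validation mode metric panel
    esp: dict[str, float]
    probabilities: pd.DataFrame  # long table of per compound-target records
    multitarget: list[MultitargetResult]
    selected: list[MultitargetResult]
    funnel: admet_mod.FunnelReport


def run_study(bundle: StudyBundle, config: RunConfig) -> StudyResult:
    """Run the full screening analysis on an in-memory study bundle."""
    bad = validate_config(config)
    if bad:
        raise ValueError("invalid config: " + "; ".join(bad))

    perf_rows = []
    esp: dict[str, float] = {}
    prob_rows = []
    calls_by_compound: dict[str, list] = {cid: [] for cid in bundle.library_ids}

    for tid in sorted(bundle.targets):
        cfg = bundle.targets[tid]
        records_kwargs: dict = {}
        if cfg.has_qsar:
            dataset = bundle.train_datasets[tid]
            train, test = stratified_split(dataset, config.split)
            model = train_forest(train, config.forest)
            test_rep = validate_on_test(model, test)
            cross_rep = cross_validate(dataset, config.forest, k=config.cv_folds)
            esp[tid] = model_esp(test_rep, cross_rep)
            for rep in (test_rep, cross_rep):
                perf_rows.append(
                    {"target_id": tid, "validation": rep.validation_mode,
                     **rep.as_dict()}
                )
            domain = fit_apd(train.X, z=config.apd_z)
            lib_X = bundle.library_X[tid]
            probs = predict_activity_probability(model, lib_X)
            flags, _ = in_domain(domain, lib_X.values)
            records_kwargs["p_activity"] = dict(zip(lib_X.compound_ids, probs))
            records_kwargs["in_domain"] = dict(zip(lib_X.compound_ids, flags))
            log.info("%s: trained forest, ESP=%.3f", tid, esp[tid])
        ligand_prob = None
        if cfg.has_docking:
            table = bundle.docking_tables[tid]
            records_kwargs["docking"] = table
            ligand_prob = table.ligand_probability
        records = fuse(
            bundle.library_ids, cfg, esp=esp.get(tid), **records_kwargs
        )
        for rec in records:
            prob_rows.append(
                {"compound_id": rec.compound_id, "target_id": tid,
                 "p_activity": rec.p_activity, "prob_dc": rec.prob_dc,
                 "prob_comb": rec.prob_comb, "in_domain": rec.in_domain}
            )
            calls_by_compound[rec.compound_id].append(
                call_target(rec, cfg, ligand_prob=ligand_prob,
                            threshold=config.probability_threshold)
            )

    results = [
        MultitargetResult(compound_id=cid, calls=calls)
        for cid, calls in calls_by_compound.items()
    ]
    selected = select_multitarget(results, min_targets=config.min_targets)
    selected_ids = {r.compound_id for r in selected}
    funnel = admet_mod.admet_funnel(
        [p for p in bundle.admet_profiles if p.compound_id in selected_ids],
        stages=config.admet_stages,
    )
    log.info(
        "screened %d compounds: %d multitarget (>=%d), %d past the ADMET funnel",
        len(bundle.library_ids), len(selected), config.min_targets,
        len(funnel.final_survivors),
    )
    return StudyResult(
        performance=pd.DataFrame(perf_rows),
        esp=esp,
        probabilities=pd.DataFrame(prob_rows),
        multitarget=results,
        selected=selected,
        funnel=funnel,
    )


# ---------------------------------------------------------------------------
# bundle serialisation: everything is plain CSV plus a JSON manifest

def write_bundle(bundle: StudyBundle, out_dir: str | Path) -> None:
    """Write a study bundle to CSV files plus a manifest JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    target_meta = {}
    for tid in sorted(bundle.targets):
        cfg = bundle.targets[tid]
        target_meta[tid] = asdict(cfg)
        if cfg.has_qsar:
            ds = bundle.train_datasets[tid]
            df = ds.X.to_frame()
            df.insert(0, "label", ds.y)
            df.to_csv(out / f"train_{tid}.csv", index_label="compound_id")
            bundle.library_X[tid].to_frame().to_csv(
                out / f"library_{tid}.csv", index_label="compound_id"
            )
        if cfg.has_docking:
            table = bundle.docking_tables[tid]
            rows = [
                {"compound_id": cid, "score": s} for cid, s in table.entries.items()
            ]
            rows.append({"compound_id": LIGAND_ROW_ID, "score": table.e_inib})
            pd.DataFrame(rows).to_csv(out / f"docking_{tid}.csv", index=False)
    admet_profiles_to_frame(bundle.admet_profiles).to_csv(
        out / "admet.csv", index=False
    )
    manifest = {
        "seed": bundle.spec.seed,
        "n_library": bundle.spec.n_library,
        "separation": bundle.spec.separation,
        "targets": target_meta,
        "planted_ids": sorted(bundle.planted_ids),
        "library_ids": bundle.library_ids,
    }
    (out / "bundle_manifest.json").write_text(json.dumps(manifest, indent=1))


def read_bundle(in_dir: str | Path) -> StudyBundle:
    """Read a study bundle previously written by :func:`write_bundle`."""
    from .synthdata import SimSpec

    src = Path(in_dir)
    manifest = json.loads((src / "bundle_manifest.json").read_text())
    targets = {
        tid: TargetConfig(**meta) for tid, meta in manifest["targets"].items()
    }
    train_datasets, library_X, docking_tables = {}, {}, {}
    for tid, cfg in targets.items():
        if cfg.has_qsar:
            df = pd.read_csv(src / f"train_{tid}.csv", index_col="compound_id")
            y = df.pop("label").to_numpy(int)
            train_datasets[tid] = LabeledDataset(
                target=cfg, X=DescriptorMatrix.from_frame(df), y=y
            )
            lib = pd.read_csv(src / f"library_{tid}.csv", index_col="compound_id")
            library_X[tid] = DescriptorMatrix.from_frame(lib)
        if cfg.has_docking:
            df = read_table(src / f"docking_{tid}.csv", schema="docking")
            docking_tables[tid] = DockingEnergyTable.from_frame(tid, df)
    admet_profiles = admet_mod.profiles_from_frame(
        read_table(src / "admet.csv", schema="admet")
    )
    spec = SimSpec(
        seed=manifest["seed"],
        separation=manifest["separation"],
        n_library=manifest["n_library"],
        n_planted=len(manifest["planted_ids"]),
    )
    return StudyBundle(
        spec=spec,
        targets=targets,
        train_datasets=train_datasets,
        library_ids=[str(i) for i in manifest["library_ids"]],
        library_X=library_X,
        docking_tables=docking_tables,
        admet_profiles=admet_profiles,
        planted_ids=set(manifest["planted_ids"]),
    )


def run_all(config: RunConfig) -> dict[str, Path]:
    """File-to-file run: read the bundle, run the study, write all outputs.

    Outputs: performance.csv, probabilities.csv, multitarget.csv, funnel.csv
    and manifest.json (config hash + seed) in ``config.output_dir``.
    """
    if config.input_dir is None or config.output_dir is None:
        raise ValueError("run_all needs config.input_dir and config.output_dir")
    bundle = read_bundle(config.input_dir)
    result = run_study(bundle, config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def write(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path

    write("performance", result.performance)
    write("probabilities", result.probabilities)
    mt = results_to_frame(result.multitarget).sort_values("compound_id")
    write("multitarget", mt)
    write("funnel", result.funnel.to_frame())
    selected = results_to_frame(result.selected)
    write("selected", selected)
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "esp": result.esp,
        "n_selected": len(result.selected),
        "final_survivors": result.funnel.final_survivors,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    paths["manifest"] = manifest_path
    return paths
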