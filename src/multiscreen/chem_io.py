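"""Compound, descriptor, docking-table and ADMET-table I/O plus target configuration.

Compound structures come in as SMILES (one per line, optional id), SDF, or CSV;
activity labels are derived from pIC50 values against a per-target potency
threshold; docking energies and ADMET properties are consumed as CSV tables
exported from external docking/ADMET software.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Compound",
    "DescriptorMatrix",
    "TargetConfig",
    "LabeledDataset",
    "ReadReport",
    "DEFAULT_TARGETS",
    "LIGAND_ROW_ID",
    "read_compounds",
    "label_by_threshold",
    "read_table",
    "compute_descriptors",
    "available_descriptor_backends",
]

#: reserved compound id marking the crystallographic reference ligand row
#: in a docking-score CSV.
LIGAND_ROW_ID = "LIGAND_PDB"


class SchemaError(ValueError):
    """A table is missing required columns or violates its schema."""


@dataclass(frozen=True)
class Compound:
    """A screened molecule: unique id, optional SMILES and free-text name."""

    id: str
    smiles: str | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("Compound id must be non-empty")


@dataclass
class DescriptorMatrix:
    """Dense descriptor block: rows are compounds, columns named descriptors."""

    compound_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.compound_ids), len(self.descriptor_names)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.compound_ids)} compounds x "
                f"{len(self.descriptor_names)} descriptors"
            )
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise ValueError("duplicate compound ids in descriptor matrix")

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.compound_ids, columns=self.descriptor_names
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DescriptorMatrix":
        return cls(
            compound_ids=[str(i) for i in frame.index],
            descriptor_names=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class TargetConfig:
    """One enzyme target: which models exist for it and its potency cutoff.

    ``activity_threshold`` is in pIC50 units (−log10 IC50 in mol/L); it is
    None for targets labelled by a binary assay rather than a potency value.
    """

    target_id: str
    activity_threshold: float | None = None
    has_qsar: bool = True
    has_docking: bool = True

    def __post_init__(self) -> None:
        if not (self.has_qsar or self.has_docking):
            raise ValueError(
                f"target {self.target_id}: at least one of has_qsar/has_docking "
                "must be true"
            )
        if self.activity_threshold is not None and self.activity_threshold <= 0:
            raise ValueError(
                f"target {self.target_id}: activity_threshold must be positive"
            )

    @property
    def mode(self) -> str:
        if self.has_qsar and self.has_docking:
            return "combined"
        return "qsar_only" if self.has_qsar else "docking_only"


#: The eight enzyme targets of the study with their curation pIC50 cutoffs.
#: Nrf2 (NFR2) uses binary activation data, NOX1 has no docking structure,
#: and NQO1 has docking only.
DEFAULT_TARGETS: dict[str, TargetConfig] = {
    cfg.target_id: cfg
    for cfg in [
        TargetConfig("JNK-3", activity_threshold=6.0),
        TargetConfig("PTP1B", activity_threshold=5.0),
        TargetConfig("NFR2", activity_threshold=None, has_docking=False),
        TargetConfig("NOX1", activity_threshold=4.75, has_docking=False),
        TargetConfig("PDE5", activity_threshold=7.0),
        TargetConfig("COX2", activity_threshold=5.50),
        TargetConfig("iNOS", activity_threshold=5.50),
        TargetConfig("NQO1", activity_threshold=None, has_qsar=False),
    ]
}


@dataclass
class LabeledDataset:
    """Descriptor matrix plus binary activity labels for one target."""

    target: TargetConfig
    X: DescriptorMatrix
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if len(self.y) != self.X.n_compounds:
            raise ValueError("label vector length does not match descriptor rows")
        if set(np.unique(self.y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")

    @property
    def n_active(self) -> int:
        return int(self.y.sum())

    @property
    def n_inactive(self) -> int:
        return int(len(self.y) - self.y.sum())


@dataclass
class ReadReport:
    """Parse outcome: accepted records plus explicitly reported rejections."""

    compounds: list[Compound] = field(default_factory=list)
    rejected: list[tuple[str, str]] = field(default_factory=list)  # (record, reason)


def _check_unique_ids(compounds: Sequence[Compound]) -> None:
    seen: dict[str, int] = {}
    for c in compounds:
        seen[c.id] = seen.get(c.id, 0) + 1
    dupes = sorted(k for k, v in seen.items() if v > 1)
    if dupes:
        raise ValueError(f"duplicate compound ids: {', '.join(dupes)}")


def _parse_smiles(smiles: str):
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    return Chem.MolFromSmiles(smiles)


def read_compounds(path: str | Path, format: str | None = None) -> ReadReport:
    """Read compounds from a SMILES, SDF or CSV file.

    SMILES files hold one record per line: ``SMILES [id]`` (whitespace
    separated; a missing id becomes its 1-based line number). CSV files need
    columns ``smiles`` and ``id`` (``name`` optional). SDF titles become ids.

    Unparseable records are reported in ``ReadReport.rejected``, never
    silently dropped. An empty file or duplicate ids raise ``ValueError``.
    """
    path = Path(path)
    if format is None:
        format = {".sdf": "sdf", ".csv": "csv"}.get(path.suffix.lower(), "smiles")
    if format not in {"sdf", "smiles", "csv"}:
        raise ValueError(f"unknown compound format: {format!r}")

    report = ReadReport()
    if format == "smiles":
        lines = [
            ln.strip() for ln in path.read_text().splitlines() if ln.strip()
        ]
        if not lines:
            raise ValueError(f"empty compound file: {path}")
        for i, line in enumerate(lines, start=1):
            parts = line.split()
            smi = parts[0]
            cid = parts[1] if len(parts) > 1 else str(i)
            if _parse_smiles(smi) is None:
                report.rejected.append((line, "invalid SMILES"))
            else:
                report.compounds.append(Compound(id=cid, smiles=smi))
    elif format == "csv":
        df = pd.read_csv(path)
        if df.empty:
            raise ValueError(f"empty compound file: {path}")
        for col in ("id", "smiles"):
            if col not in df.columns:
                raise SchemaError(f"compound CSV missing required column: {col}")
        for _, row in df.iterrows():
            smi = str(row["smiles"])
            if _parse_smiles(smi) is None:
                report.rejected.append((smi, "invalid SMILES"))
            else:
                report.compounds.append(
                    Compound(
                        id=str(row["id"]),
                        smiles=smi,
                        name=str(row["name"]) if "name" in df.columns else None,
                    )
                )
    else:  # sdf
        from rdkit import Chem

        supplier = Chem.SDMolSupplier(str(path))
        n_records = 0
        for i, mol in enumerate(supplier):
            n_records += 1
            if mol is None:
                report.rejected.append((f"record {i}", "unparseable SDF record"))
                continue
            title = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            cid = title or str(i + 1)
            report.compounds.append(
                Compound(id=cid, smiles=Chem.MolToSmiles(mol), name=title or None)
            )
        if n_records == 0:
            raise ValueError(f"empty compound file: {path}")

    _check_unique_ids(report.compounds)
    return report


def label_by_threshold(
    records: Iterable[tuple[str, float]], threshold: float
) -> tuple[dict[str, int], list[str]]:
    """Binarise pIC50 values: active (1) iff pIC50 >= threshold.

    The tie goes to active, matching the study's labelling convention
    (e.g. "pIC50 >= 6.0" counted as active). Records with missing (NaN/None)
    pIC50 are excluded and their ids returned in the second element.

    Returns
    -------
    (labels, excluded) : dict of id -> {0,1}, list of excluded ids
    """
    labels: dict[str, int] = {}
    excluded: list[str] = []
    for cid, pic50 in records:
        if pic50 is None or not np.isfinite(pic50):
            excluded.append(cid)
            continue
        labels[cid] = int(pic50 >= threshold)
    return labels, excluded


_TABLE_SCHEMAS = {
    "docking": ["compound_id", "score"],
    "admet": [
        "compound_id",
        "mw",
        "consensus_logp",
        "hbd",
        "hba",
        "rotatable_bonds",
        "solubility_class",
        "pgp_substrate",
        "bbb_permeant",
    ],
    "probabilities": ["compound_id", "target_id"],
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a typed CSV table, validating the schema's required columns.

    ``schema`` is one of ``docking`` (compound_id, score; the reference-ligand
    row uses the reserved id ``LIGAND_PDB``), ``admet`` (physicochemical,
    pharmacokinetic and toxicity fields) or ``probabilities``. Unknown columns
    are preserved. A missing required column raises ``SchemaError`` naming it.
    """
    if schema not in _TABLE_SCHEMAS:
        raise ValueError(f"unknown table schema: {schema!r}")
    df = pd.read_csv(Path(path))
    for col in _TABLE_SCHEMAS[schema]:
        if col not in df.columns:
            raise SchemaError(f"{schema} table missing required column: {col}")
    df["compound_id"] = df["compound_id"].astype(str)
    if schema == "docking" and not np.all(np.isfinite(df["score"].to_numpy(float))):
        raise SchemaError("docking table contains non-finite scores")
    return df


def _rdkit_2d_descriptors(compounds: Sequence[Compound]) -> pd.DataFrame:
    from rdkit import Chem
    from rdkit.Chem import Descriptors

    names = [n for n, _ in Descriptors.descList]
    calc = dict(Descriptors.descList)
    rows = []
    for c in compounds:
        mol = Chem.MolFromSmiles(c.smiles) if c.smiles else None
        if mol is None:
            raise ValueError(f"compound {c.id} has no parseable structure")
        rows.append([float(calc[n](mol)) for n in names])
    return pd.DataFrame(rows, index=[c.id for c in compounds], columns=names)


_DESCRIPTOR_BACKENDS = {"rdkit2d": _rdkit_2d_descriptors}


def available_descriptor_backends() -> list[str]:
    return sorted(_DESCRIPTOR_BACKENDS)


def compute_descriptors(
    compounds: Sequence[Compound], backend: str = "rdkit2d"
) -> DescriptorMatrix:
    """Compute a curated molecular-descriptor matrix.

    The backend is pluggable; the default computes the full RDKit 2D
    descriptor set. Curation drops columns that are constant or contain any
    non-finite value, so the returned matrix is dense and informative.
    Deterministic for a fixed backend and input order.
    """
    if backend not in _DESCRIPTOR_BACKENDS:
        raise ValueError(
            f"unknown descriptor backend {backend!r}; "
            f"available: {available_descriptor_backends()}"
        )
    frame = _DESCRIPTOR_BACKENDS[backend](compounds)
    finite = frame.replace([np.inf, -np.inf], np.nan)
    keep = finite.notna().all(axis=0) & (finite.nunique(axis=0) > 1)
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(
            f"descriptor curation dropped {dropped} constant/non-finite columns",
            stacklevel=2,
        )
    return DescriptorMatrix.from_frame(finite.loc[:, keep])
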