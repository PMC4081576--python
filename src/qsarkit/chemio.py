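"""Compound, activity and docking-energy I/O.

Reads SMILES/SDF structure files joined against activity tables (IC50 in nM
plus a wild/mutant class label), converts IC50 to pIC50, loads the seven
AutoDock-style per-compound energy terms, and produces reproducible
train/validation splits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

TARGET_CLASSES = ("wild", "mutant")

#: Canonical column order of a docking-energy table (kcal/mol).
ENERGY_COLUMNS = (
    "E_FreeBind",
    "E_InterMol",
    "E_VHD",
    "E_Elec",
    "E_FToT",
    "E_Tors",
    "E_Unb",
)


class ChemIOError(ValueError):
    """Raised on malformed structure/activity/energy inputs."""


def ic50_to_pic50(ic50_nM: float, *, molar: bool = True) -> float:
    """Convert an IC50 in nanomolar to pIC50.

    Under the standard medicinal-chemistry (molar) convention,
    pIC50 = −log10(IC50 [M]) = 9 − log10(IC50 [nM]).  With ``molar=False``
    the raw-nM variant −log10(IC50 [nM]) is returned instead.
    """
    if not (ic50_nM > 0) or not math.isfinite(ic50_nM):
        raise ChemIOError(f"IC50 must be a positive finite value in nM, got {ic50_nM!r}")
    if molar:
        return 9.0 - math.log10(ic50_nM)
    return -math.log10(ic50_nM)


def pic50_to_ic50(pic50: float, *, molar: bool = True) -> float:
    """Inverse of :func:`ic50_to_pic50`; returns IC50 in nM."""
    if not math.isfinite(pic50):
        raise ChemIOError(f"pIC50 must be finite, got {pic50!r}")
    if molar:
        return 10.0 ** (9.0 - pic50)
    return 10.0 ** (-pic50)


@dataclass(frozen=True)
class Compound:
    """One inhibitor: structure, measured potency and target-class label."""

    compound_id: str
    smiles: str
    ic50: float  # nM
    pic50: float  # log units, molar convention by default
    target_class: str  # "wild" | "mutant"

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ChemIOError(f"{self.compound_id}: IC50 must be positive, got {self.ic50}")
        if not math.isfinite(self.pic50):
            raise ChemIOError(f"{self.compound_id}: pIC50 is not finite")
        if self.target_class not in TARGET_CLASSES:
            raise ChemIOError(
                f"{self.compound_id}: target_class must be one of {TARGET_CLASSES}, "
                f"got {self.target_class!r}"
            )


@dataclass(frozen=True)
class DockingEnergyRecord:
    """Seven per-compound docking energy terms (kcal/mol)."""

    compound_id: str
    E_FreeBind: float
    E_InterMol: float
    E_VHD: float
    E_Elec: float
    E_FToT: float
    E_Tors: float
    E_Unb: float

    def energies(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in ENERGY_COLUMNS}

    def __post_init__(self) -> None:
        for c in ENERGY_COLUMNS:
            v = getattr(self, c)
            if not math.isfinite(v):
                raise ChemIOError(f"{self.compound_id}: energy {c} is not finite ({v!r})")


@dataclass(frozen=True)
class DatasetSplit:
    """A reproducible train/validation partition of compound ids."""

    train_ids: tuple[str, ...]
    valid_ids: tuple[str, ...]
    seed: int
    fraction_valid: float | None = None
    explicit_counts: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.valid_ids)
        if overlap:
            raise ChemIOError(f"train/valid overlap: {sorted(overlap)}")


def _read_structures(path: str | Path, on_invalid: str) -> list[tuple[str, str]]:
    """Return (compound_id, canonical smiles) pairs from a SMILES or SDF file."""
    path = Path(path)
    records: list[tuple[str, str]] = []
    skipped: list[str] = []

    if path.suffix.lower() == ".sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                skipped.append(f"record #{i + 1}")
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol_{i + 1}"
            records.append((name, Chem.MolToSmiles(mol)))
    else:
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ChemIOError(
                    f"{path}:{lineno}: expected 'SMILES whitespace compound_id', got {line!r}"
                )
            smi, cid = parts[0], parts[1]
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                skipped.append(f"{cid} (line {lineno})")
                continue
            records.append((cid, Chem.MolToSmiles(mol)))

    if skipped:
        msg = f"{path}: {len(skipped)} unparseable structure(s): {', '.join(skipped)}"
        if on_invalid == "abort":
            raise ChemIOError(msg)
        warnings.warn(msg, stacklevel=3)
    return records


def load_compounds(
    structures_path: str | Path,
    activity_path: str | Path,
    *,
    on_invalid: Literal["abort", "skip"] = "abort",
    molar: bool = True,
) -> list[Compound]:
    """Join a structure file with an activity CSV into Compound records.

    The activity CSV must carry columns ``compound_id``, ``ic50_nM`` and
    ``target_class``.  Every structure must have exactly one activity row and
    vice versa; orphans on either side are a hard error.  Invalid SMILES abort
    by default (``on_invalid="skip"`` logs and drops them instead).
    """
    structures = _read_structures(structures_path, on_invalid)
    ids = [cid for cid, _ in structures]
    dup = {c for c in ids if ids.count(c) > 1}
    if dup:
        raise ChemIOError(f"duplicate compound ids in structures: {sorted(dup)}")

    act = pd.read_csv(activity_path, dtype={"compound_id": str})
    for col in ("compound_id", "ic50_nM", "target_class"):
        if col not in act.columns:
            raise ChemIOError(f"{activity_path}: missing column {col!r}")
    if act["compound_id"].duplicated().any():
        d = act.loc[act["compound_id"].duplicated(), "compound_id"].tolist()
        raise ChemIOError(f"duplicate compound ids in activity table: {d}")

    smiles_by_id = dict(structures)
    act_ids = set(act["compound_id"])
    orphan_structures = sorted(set(smiles_by_id) - act_ids)
    orphan_activity = sorted(act_ids - set(smiles_by_id))
    if orphan_structures or orphan_activity:
        raise ChemIOError(
            "structure/activity join mismatch: "
            f"{len(orphan_structures)} structure(s) without activity {orphan_structures}; "
            f"{len(orphan_activity)} activity row(s) without structure {orphan_activity}"
        )

    compounds = []
    for row in act.itertuples(index=False):
        ic50 = float(row.ic50_nM)
        if not ic50 > 0:
            raise ChemIOError(
                f"activity row for {row.compound_id!r}: ic50_nM must be positive, got {ic50}"
            )
        compounds.append(
            Compound(
                compound_id=str(row.compound_id),
                smiles=smiles_by_id[str(row.compound_id)],
                ic50=ic50,
                pic50=ic50_to_pic50(ic50, molar=molar),
                target_class=str(row.target_class),
            )
        )
    return compounds


def write_compounds(
    compounds: Sequence[Compound],
    structures_path: str | Path,
    activity_path: str | Path,
) -> None:
    """Write a compound set back to a SMILES file + activity CSV."""
    lines = [f"{c.smiles} {c.compound_id}" for c in compounds]
    Path(structures_path).write_text("\n".join(lines) + "\n")
    pd.DataFrame(
        {
            "compound_id": [c.compound_id for c in compounds],
            "ic50_nM": [repr(c.ic50) for c in compounds],
            "target_class": [c.target_class for c in compounds],
        }
    ).to_csv(activity_path, index=False)


def split_dataset(
    compounds: Sequence[Compound],
    fraction_valid: float | None = 0.2,
    seed: int = 0,
    explicit_counts: tuple[int, int] | None = None,
) -> DatasetSplit:
    """Randomly partition compounds into train/validation sets.

    Validation size is floor(fraction_valid * n) unless ``explicit_counts``
    (n_train, n_valid) is given.  Sampling is uniform without replacement and
    fully determined by ``seed``.
    """
    n = len(compounds)
    if n < 2:
        raise ChemIOError(f"need at least 2 compounds to split, got {n}")
    ids = [c.compound_id for c in compounds]
    if len(set(ids)) != n:
        raise ChemIOError("compound ids are not unique")

    if explicit_counts is not None:
        n_train, n_valid = explicit_counts
        if n_train + n_valid != n or n_train < 0 or n_valid < 0:
            raise ChemIOError(
                f"explicit_counts {explicit_counts} do not sum to n={n}"
            )
    else:
        if fraction_valid is None or not (0 < fraction_valid < 1):
            raise ChemIOError(f"fraction_valid must be in (0,1), got {fraction_valid}")
        n_valid = int(math.floor(fraction_valid * n))
        n_train = n - n_valid

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    valid_ids = tuple(ids[i] for i in sorted(order[:n_valid]))
    train_ids = tuple(ids[i] for i in sorted(order[n_valid:]))
    return DatasetSplit(
        train_ids=train_ids,
        valid_ids=valid_ids,
        seed=seed,
        fraction_valid=None if explicit_counts is not None else fraction_valid,
        explicit_counts=explicit_counts,
    )


def load_docking_energies(
    path: str | Path,
    *,
    on_missing: Literal["abort", "drop"] = "abort",
) -> list[DockingEnergyRecord]:
    """Load a docking-energy CSV into records.

    The CSV must have a ``compound_id`` column plus all seven energy columns.
    Rows with missing/non-finite energies abort by default; under
    ``on_missing="drop"`` they are dropped with a warning.
    """
    df = pd.read_csv(path, dtype={"compound_id": str})
    if "compound_id" not in df.columns:
        raise ChemIOError(f"{path}: missing column 'compound_id'")
    for col in ENERGY_COLUMNS:
        if col not in df.columns:
            raise ChemIOError(f"{path}: missing column {col}")
    if df["compound_id"].duplicated().any():
        d = df.loc[df["compound_id"].duplicated(), "compound_id"].tolist()
        raise ChemIOError(f"{path}: duplicate compound ids {d}")

    records: list[DockingEnergyRecord] = []
    dropped: list[str] = []
    for row in df.itertuples(index=False):
        vals = {c: getattr(row, c) for c in ENERGY_COLUMNS}
        bad = [c for c, v in vals.items() if pd.isna(v) or not math.isfinite(float(v))]
        if bad:
            if on_missing == "abort":
                raise ChemIOError(
                    f"{path}: compound {row.compound_id!r} has missing/non-finite {bad}"
                )
            dropped.append(str(row.compound_id))
            continue
        records.append(
            DockingEnergyRecord(compound_id=str(row.compound_id), **{c: float(v) for c, v in vals.items()})
        )
    if dropped:
        warnings.warn(
            f"{path}: dropped {len(dropped)} compound(s) with missing energies: {dropped}",
            stacklevel=2,
        )
    return records


def write_docking_energies(
    records: Iterable[DockingEnergyRecord], path: str | Path
) -> None:
    rows = [{"compound_id": r.compound_id, **r.energies()} for r in records]
    pd.DataFrame(rows, columns=["compound_id", *ENERGY_COLUMNS]).to_csv(path, index=False)
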