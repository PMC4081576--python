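"""Molecular descriptor matrices and docking-energy feature fusion.

One open descriptor engine (RDKit) provides the descriptor families a QSAR
pipeline needs: continuous physicochemical, topological and constitutional
blocks, plus three binary fingerprint families (curated substructure keys,
hashed path-based bits, MACCS keys).  Docking energies computed elsewhere are
appended as ordinary feature columns and can be pre-screened for pairwise
correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, GraphDescriptors, MACCSkeys, rdMolDescriptors

from .chemio import ENERGY_COLUMNS, Compound, DockingEnergyRecord

PROVENANCE = ("chemical_continuous", "fingerprint_bit", "docking_energy")

FAMILIES = (
    "physicochemical",
    "topological",
    "constitutional",
    "substructure_fp",
    "path_fp",
    "maccs_like_fp",
)


class DescriptorError(ValueError):
    pass


@dataclass
class DescriptorMatrix:
    """Compounds × named feature columns with per-column provenance.

    ``data`` is indexed by compound_id; ``provenance`` maps every column to
    one of ``chemical_continuous``, ``fingerprint_bit``, ``docking_energy``.
    Fingerprint-bit columns contain only {0, 1}.
    """

    data: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        if len(set(cols)) != len(cols):
            dup = sorted({c for c in cols if cols.count(c) > 1})
            raise DescriptorError(f"duplicate column names: {dup}")
        missing = [c for c in cols if c not in self.provenance]
        if missing:
            raise DescriptorError(f"columns without provenance: {missing[:5]}...")
        for col, prov in self.provenance.items():
            if prov not in PROVENANCE:
                raise DescriptorError(f"unknown provenance {prov!r} for {col}")
        for col in cols:
            if self.provenance[col] == "fingerprint_bit":
                vals = np.asarray(self.data[col])
                if not np.isin(vals, (0, 1)).all():
                    raise DescriptorError(f"fingerprint column {col} is not binary")

    @property
    def compound_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def column_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset(self, columns: Sequence[str]) -> "DescriptorMatrix":
        missing = [c for c in columns if c not in self.data.columns]
        if missing:
            raise DescriptorError(f"unknown columns: {missing}")
        return DescriptorMatrix(
            data=self.data[list(columns)].copy(),
            provenance={c: self.provenance[c] for c in columns},
        )

    def fingerprint_columns(self) -> list[str]:
        return [c for c in self.data.columns if self.provenance[c] == "fingerprint_bit"]


# ---------------------------------------------------------------------------
# descriptor families

_PHYSICOCHEMICAL: list[tuple[str, Callable]] = [
    ("MolWt", Descriptors.MolWt),
    ("MolLogP", Crippen.MolLogP),
    ("MolMR", Crippen.MolMR),
    ("TPSA", rdMolDescriptors.CalcTPSA),
    ("NumHDonors", rdMolDescriptors.CalcNumHBD),
    ("NumHAcceptors", rdMolDescriptors.CalcNumHBA),
    ("NumRotatableBonds", rdMolDescriptors.CalcNumRotatableBonds),
    ("FractionCSP3", rdMolDescriptors.CalcFractionCSP3),
    ("LabuteASA", rdMolDescriptors.CalcLabuteASA),
    ("MaxPartialCharge", Descriptors.MaxPartialCharge),
    ("MinPartialCharge", Descriptors.MinPartialCharge),
]

_TOPOLOGICAL: list[tuple[str, Callable]] = [
    ("BalabanJ", GraphDescriptors.BalabanJ),
    ("BertzCT", GraphDescriptors.BertzCT),
    ("Chi0", GraphDescriptors.Chi0),
    ("Chi1", GraphDescriptors.Chi1),
    ("Chi0v", GraphDescriptors.Chi0v),
    ("Chi1v", GraphDescriptors.Chi1v),
    ("Chi2v", GraphDescriptors.Chi2v),
    ("Kappa1", GraphDescriptors.Kappa1),
    ("Kappa2", GraphDescriptors.Kappa2),
    ("Kappa3", GraphDescriptors.Kappa3),
    ("HallKierAlpha", GraphDescriptors.HallKierAlpha),
]


def _count_atoms(symbol: str) -> Callable:
    def f(mol: Chem.Mol) -> int:
        return sum(1 for a in mol.GetAtoms() if a.GetSymbol() == symbol)

    return f


_CONSTITUTIONAL: list[tuple[str, Callable]] = [
    ("HeavyAtomCount", lambda m: m.GetNumHeavyAtoms()),
    ("RingCount", rdMolDescriptors.CalcNumRings),
    ("AromaticRings", rdMolDescriptors.CalcNumAromaticRings),
    ("AliphaticRings", rdMolDescriptors.CalcNumAliphaticRings),
    ("NHOHCount", Descriptors.NHOHCount),
    ("NOCount", Descriptors.NOCount),
    ("nC", _count_atoms("C")),
    ("nN", _count_atoms("N")),
    ("nO", _count_atoms("O")),
    ("nS", _count_atoms("S")),
    ("nF", _count_atoms("F")),
    ("nCl", _count_atoms("Cl")),
    ("nBr", _count_atoms("Br")),
]

#: Curated substructure keys (PubChem-style role): name -> SMARTS.
SUBSTRUCTURE_KEYS: dict[str, str] = {
    "aromatic_ring": "a1aaaaa1",
    "benzene": "c1ccccc1",
    "pyridine_N": "n1ccccc1",
    "pyrimidine": "c1cncnc1",
    "fused_bicyclic_aromatic": "a1aaa2aaaaa2a1",
    "quinazoline": "c1ccc2ncncc2c1",
    "pyrazole": "c1cc[nH]n1",
    "imidazole": "c1cnc[nH]1",
    "thiazole": "c1cscn1",
    "primary_amine": "[NX3;H2;!$(NC=O)]",
    "secondary_amine": "[NX3;H1;!$(NC=O)]",
    "tertiary_amine": "[NX3;H0;!$(NC=O);!$(N=*)]",
    "aniline_N": "c[NX3]",
    "hydroxyl": "[OX2H]",
    "phenol": "c[OX2H]",
    "ether": "[OD2]([#6])[#6]",
    "methoxy": "[OX2][CH3]",
    "carbonyl": "[CX3]=[OX1]",
    "carboxylic_acid": "[CX3](=O)[OX2H1]",
    "ester": "[CX3](=O)[OX2][#6]",
    "amide": "[NX3][CX3](=[OX1])",
    "nitrile": "[CX2]#[NX1]",
    "nitro": "[NX3](=O)=O",
    "sulfonamide": "[SX4](=O)(=O)[NX3]",
    "thioether": "[SX2]([#6])[#6]",
    "fluoro": "[F]",
    "chloro": "[Cl]",
    "bromo": "[Br]",
    "trifluoromethyl": "[CX4](F)(F)F",
    "alkyne": "[CX2]#[CX2]",
    "vinyl": "[CX3]=[CX3]",
    "halo_on_aromatic": "c[F,Cl,Br,I]",
    "n_methyl": "[NX3][CH3]",
    "acetylenic_C": "[$([CX2]#C)]",
    "ring_NH": "[nH]",
}

_SUBSTRUCTURE_PATTERNS = {
    name: Chem.MolFromSmarts(sm) for name, sm in SUBSTRUCTURE_KEYS.items()
}

PATH_FP_BITS = 256


def _family_block(mol: Chem.Mol, family: str) -> dict[str, float]:
    if family == "physicochemical":
        return {f"phys_{n}": float(f(mol)) for n, f in _PHYSICOCHEMICAL}
    if family == "topological":
        return {f"topo_{n}": float(f(mol)) for n, f in _TOPOLOGICAL}
    if family == "constitutional":
        return {f"const_{n}": float(f(mol)) for n, f in _CONSTITUTIONAL}
    if family == "substructure_fp":
        return {
            f"sub_fp_{name}": float(mol.HasSubstructMatch(patt))
            for name, patt in _SUBSTRUCTURE_PATTERNS.items()
        }
    if family == "path_fp":
        fp = Chem.RDKFingerprint(mol, fpSize=PATH_FP_BITS)
        bits = set(fp.GetOnBits())
        return {f"path_fp_{i:04d}": float(i in bits) for i in range(PATH_FP_BITS)}
    if family == "maccs_like_fp":
        fp = MACCSkeys.GenMACCSKeys(mol)
        bits = set(fp.GetOnBits())
        # key 0 is unused in the 166-key MACCS definition
        return {f"maccs_fp_{i:03d}": float(i in bits) for i in range(1, 167)}
    raise DescriptorError(f"unknown descriptor family {family!r}; choose from {FAMILIES}")


_CONTINUOUS_FAMILIES = {"physicochemical", "topological", "constitutional"}


def compute_descriptor_matrix(
    compounds: Sequence[Compound],
    families: Iterable[str] = FAMILIES,
) -> DescriptorMatrix:
    """Compute the descriptor matrix for a compound set.

    Column names are prefixed by family.  Constant columns are retained —
    pruning degenerate descriptors is the selection stage's job.  The result
    is deterministic for a fixed input and RDKit version.
    """
    families = list(families)
    unknown = [f for f in families if f not in FAMILIES]
    if unknown:
        raise DescriptorError(f"unknown families {unknown}; choose from {FAMILIES}")
    if not compounds:
        raise DescriptorError("empty compound list")

    rows: list[dict[str, float]] = []
    for c in compounds:
        mol = Chem.MolFromSmiles(c.smiles)
        if mol is None:
            raise DescriptorError(f"compound {c.compound_id}: unparseable SMILES {c.smiles!r}")
        row: dict[str, float] = {}
        for fam in families:
            try:
                row.update(_family_block(mol, fam))
            except DescriptorError:
                raise
            except Exception as exc:  # pragma: no cover - engine failure path
                raise DescriptorError(
                    f"compound {c.compound_id}: descriptor family {fam!r} failed: {exc}"
                ) from exc
        rows.append(row)

    data = pd.DataFrame(rows, index=[c.compound_id for c in compounds])
    provenance = {}
    for fam in families:
        prov = "chemical_continuous" if fam in _CONTINUOUS_FAMILIES else "fingerprint_bit"
        prefix = {
            "physicochemical": "phys_",
            "topological": "topo_",
            "constitutional": "const_",
            "substructure_fp": "sub_fp_",
            "path_fp": "path_fp_",
            "maccs_like_fp": "maccs_fp_",
        }[fam]
        for col in data.columns:
            if col.startswith(prefix):
                provenance[col] = prov
    return DescriptorMatrix(data=data, provenance=provenance)


def append_docking_columns(
    matrix: DescriptorMatrix,
    energy_records: Sequence[DockingEnergyRecord],
    *,
    policy: str = "strict",
    columns: Sequence[str] | None = None,
) -> DescriptorMatrix:
    """Append docking-energy columns to a descriptor matrix.

    Under ``policy="strict"`` every compound in the matrix must have an energy
    record; ``policy="inner"`` keeps the intersection with a warning.
    ``columns`` restricts which energy terms are appended (default: all seven,
    e.g. the retained set from :func:`screen_energy_descriptors`).
    """
    ids = [r.compound_id for r in energy_records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise DescriptorError(f"duplicate energy records for {dup}")
    cols = list(columns) if columns is not None else list(ENERGY_COLUMNS)
    unknown = [c for c in cols if c not in ENERGY_COLUMNS]
    if unknown:
        raise DescriptorError(f"unknown energy columns {unknown}")

    by_id = {r.compound_id: r for r in energy_records}
    matrix_ids = matrix.compound_ids
    missing = [i for i in matrix_ids if i not in by_id]
    if missing:
        if policy == "strict":
            raise DescriptorError(
                f"{len(missing)} compound(s) without energy records: {missing}"
            )
        if policy != "inner":
            raise DescriptorError(f"unknown policy {policy!r}")
        warnings.warn(
            f"inner-join dropped {len(missing)} compound(s) without energies: {missing}",
            stacklevel=2,
        )
        matrix_ids = [i for i in matrix_ids if i in by_id]

    data = matrix.data.loc[matrix_ids].copy()
    for col in cols:
        data[col] = [getattr(by_id[i], col) for i in matrix_ids]
    provenance = dict(matrix.provenance)
    provenance.update({c: "docking_energy" for c in cols})
    return DescriptorMatrix(data=data, provenance=provenance)


def screen_energy_descriptors(
    energy_records: Sequence[DockingEnergyRecord],
    pairwise_cutoff: float = 0.9,
) -> tuple[list[str], pd.DataFrame]:
    """Screen the seven energy terms for pairwise Pearson correlation.

    Returns (retained column names, full 7×7 correlation table).  From each
    pair with |r| above the cutoff, the member with the larger mean absolute
    correlation to the remaining terms is dropped (this reproduces dropping
    the intermolecular energy when it tracks the vdW+Hbond+desolvation term).
    Constant columns have undefined correlations and are auto-dropped.
    """
    if len(energy_records) < 3:
        raise DescriptorError(f"need >=3 records to correlate, got {len(energy_records)}")
    df = pd.DataFrame(
        [r.energies() for r in energy_records],
        index=[r.compound_id for r in energy_records],
        columns=list(ENERGY_COLUMNS),
    )
    corr = df.corr(method="pearson")  # NaN where a column is constant

    retained = [c for c in ENERGY_COLUMNS]
    constant = [c for c in retained if np.isclose(df[c].std(ddof=0), 0.0)]
    if constant:
        warnings.warn(f"constant energy column(s) auto-dropped: {constant}", stacklevel=2)
        retained = [c for c in retained if c not in constant]

    while True:
        sub = corr.loc[retained, retained].abs()
        np.fill_diagonal(sub.values, 0.0)
        if sub.size == 0 or float(sub.max().max()) <= pairwise_cutoff:
            break
        # worst offending pair, deterministic by (−|r|, names)
        pairs = [
            (sub.iat[i, j], retained[i], retained[j])
            for i in range(len(retained))
            for j in range(i + 1, len(retained))
            if sub.iat[i, j] > pairwise_cutoff
        ]
        pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
        _, a, b = pairs[0]
        others = [c for c in retained if c not in (a, b)]
        if others:
            mean_a = sub.loc[a, others].mean()
            mean_b = sub.loc[b, others].mean()
        else:
            mean_a = mean_b = 0.0
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:
            drop = max(a, b)  # lexicographically later
        retained = [c for c in retained if c != drop]
    return retained, corr
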