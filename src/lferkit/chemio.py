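"""Molecular input/output: formulas, structures, carbon environments, compound tables.

The descriptor framework in this package needs remarkably little structural
information: element counts (for the size descriptor), sp3-carbon branching
environments, and bond-level rotatability context. This module provides those
primitives on top of rdkit, plus CSV-backed compound tables that carry
descriptors and observed properties through fitting and validation.

Scope note: the framework covers *neutral* organic compounds built from
C, H, O, N, S, F, Cl, Br and I; charged or radical species and other
elements are rejected rather than silently coerced.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from rdkit import Chem

from .errors import FormulaParseError, StructureError, TableError, UnsupportedElement

SUPPORTED_ELEMENTS: tuple[str, ...] = ("C", "H", "O", "N", "S", "F", "Cl", "Br", "I")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count map for a neutral organic compound.

    Only the nine supported elements may appear, every count is a
    non-negative integer, and at least one atom must be present.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for sym, cnt in self.counts.items():
            if sym not in SUPPORTED_ELEMENTS:
                raise UnsupportedElement(sym)
            if not isinstance(cnt, int) or cnt < 0:
                raise ValueError(f"count for {sym} must be a non-negative integer, got {cnt!r}")
            if cnt > 0:
                clean[sym] = cnt
        if not clean:
            raise ValueError("formula must contain at least one atom")
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for sym, cnt in other.counts.items():
            merged[sym] = merged.get(sym, 0) + cnt
        return MolecularFormula(merged)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MolecularFormula):
            return NotImplemented
        return dict(self.counts) == dict(other.counts)

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.counts.items())))

    def hill(self) -> str:
        """Canonical Hill-notation string: C, H, then other elements alphabetically."""
        parts: list[str] = []
        symbols = sorted(self.counts)
        if "C" in self.counts:
            ordered = ["C"] + (["H"] if "H" in self.counts else [])
            ordered += [s for s in symbols if s not in ("C", "H")]
        else:
            ordered = symbols
        for sym in ordered:
            n = self.counts[sym]
            parts.append(sym if n == 1 else f"{sym}{n}")
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill()


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation molecular formula such as ``"C6H6O2"``.

    An absent count means 1. Raises :class:`UnsupportedElement` for elements
    outside the supported nine and :class:`FormulaParseError` (with the
    character position) for malformed input.
    """
    if not text or not text.strip():
        raise FormulaParseError(text, 0, "empty formula")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaParseError(text, pos, f"unexpected character {text[pos]!r}")
        sym, digits = m.group(1), m.group(2)
        if sym not in SUPPORTED_ELEMENTS:
            raise UnsupportedElement(sym)
        if digits == "":
            n = 1
        else:
            n = int(digits)
            if n == 0:
                raise FormulaParseError(text, m.start(2), f"zero count for element {sym}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return MolecularFormula(counts)


def format_formula(formula: MolecularFormula) -> str:
    """Canonical Hill serialization; inverse of :func:`parse_formula`."""
    return formula.hill()


@dataclass
class Molecule:
    """A neutral organic structure with an identifier.

    Wraps an rdkit molecule (hydrogens implicit) together with the raw
    source record it was parsed from.
    """

    id: str
    rdmol: Chem.Mol
    source: str = ""

    @property
    def formula(self) -> MolecularFormula:
        return formula_from_mol(self)


def _validate_rdmol(rdmol: Chem.Mol, source: str) -> None:
    if Chem.GetFormalCharge(rdmol) != 0:
        raise StructureError(f"charged species rejected (net charge {Chem.GetFormalCharge(rdmol)}): {source!r}")
    for atom in rdmol.GetAtoms():
        if atom.GetFormalCharge() != 0:
            raise StructureError(f"atom-level formal charge in {source!r}; only neutral compounds are in scope")
        if atom.GetNumRadicalElectrons() != 0:
            raise StructureError(f"radical species rejected: {source!r}")
        if atom.GetSymbol() not in SUPPORTED_ELEMENTS:
            raise UnsupportedElement(atom.GetSymbol())


def mol_from_smiles(smiles: str, mol_id: str | None = None) -> Molecule:
    """Parse a SMILES string into a validated neutral :class:`Molecule`."""
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise StructureError(f"cannot parse SMILES {smiles!r}")
    _validate_rdmol(rdmol, smiles)
    return Molecule(id=mol_id if mol_id is not None else smiles, rdmol=rdmol, source=smiles)


def formula_from_mol(mol: Molecule) -> MolecularFormula:
    """Element tally (including implicit hydrogens) of a parsed structure."""
    counts: dict[str, int] = {}
    for atom in mol.rdmol.GetAtoms():
        sym = atom.GetSymbol()
        counts[sym] = counts.get(sym, 0) + 1
        h = atom.GetTotalNumHs()
        if h:
            counts["H"] = counts.get("H", 0) + h
    return MolecularFormula(counts)


@dataclass(frozen=True)
class CarbonEnvironmentCounts:
    """Branched sp3-carbon environment counts used by the size descriptor.

    ``n_c3`` counts sp3 carbons bonded to exactly three heavy atoms,
    ``n_c4`` those bonded to exactly four — fluorine neighbors are not
    counted as heavy in either tally (all other non-hydrogen neighbors,
    including Cl/Br/I, are).
    """

    n_c3: int = 0
    n_c4: int = 0

    def __post_init__(self) -> None:
        if self.n_c3 < 0 or self.n_c4 < 0:
            raise ValueError("environment counts must be non-negative")

    def __add__(self, other: "CarbonEnvironmentCounts") -> "CarbonEnvironmentCounts":
        return CarbonEnvironmentCounts(self.n_c3 + other.n_c3, self.n_c4 + other.n_c4)


def perceive_carbon_environments(mol: Molecule) -> CarbonEnvironmentCounts:
    """Count branched sp3 carbons (N_c3, N_c4) in a structure.

    A carbon qualifies when rdkit perceives it as sp3 and its number of
    non-hydrogen, non-fluorine neighbors is exactly 3 (N_c3) or 4 (N_c4).
    Molecules without sp3 carbons yield (0, 0).
    """
    n_c3 = n_c4 = 0
    for atom in mol.rdmol.GetAtoms():
        if atom.GetSymbol() != "C":
            continue
        if atom.GetHybridization() != Chem.HybridizationType.SP3:
            continue
        heavy = sum(
            1 for nbr in atom.GetNeighbors() if nbr.GetSymbol() not in ("H", "F")
        )
        if heavy == 3:
            n_c3 += 1
        elif heavy == 4:
            n_c4 += 1
    return CarbonEnvironmentCounts(n_c3, n_c4)


def read_smiles_file(path: str | Path) -> list[Molecule]:
    """Read a .smi file: one record per line, ``SMILES<whitespace>id``."""
    mols: list[Molecule] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        mol_id = parts[1].strip() if len(parts) > 1 else f"line{lineno}"
        mols.append(mol_from_smiles(smiles, mol_id))
    return mols


def read_sdf(path: str | Path) -> list[Molecule]:
    """Read a V2000 SDF file into validated molecules (record name as id)."""
    mols: list[Molecule] = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=True)
    for i, rdmol in enumerate(supplier):
        if rdmol is None:
            raise StructureError(f"unparseable SDF record #{i + 1} in {path}")
        _validate_rdmol(rdmol, f"{path}#{i + 1}")
        name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") and rdmol.GetProp("_Name") else f"mol{i + 1}"
        mols.append(Molecule(id=name, rdmol=rdmol, source=f"{path}#{i + 1}"))
    return mols


@dataclass
class CompoundTable:
    """Tabular compound data: identifiers, structures, descriptors, properties.

    Thin wrapper over a pandas DataFrame with unique string ids in column
    ``id`` and a role map describing what each column is (``structure``,
    ``formula``, ``descriptor``, ``property``). Missing values are NaN and
    round-trip as empty CSV cells.
    """

    df: pd.DataFrame
    roles: dict[str, str] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "id" not in self.df.columns:
            raise TableError("compound table requires an 'id' column")
        ids = self.df["id"].astype(str)
        dupes = ids[ids.duplicated()].unique().tolist()
        if dupes:
            raise TableError(f"duplicate compound ids: {', '.join(map(str, dupes))}")
        self.df = self.df.reset_index(drop=True)
        self.df["id"] = ids

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> list[str]:
        return self.df["id"].tolist()

    def column(self, name: str) -> pd.Series:
        if name not in self.df.columns:
            raise TableError(f"column {name!r} not present; have {list(self.df.columns)}")
        return self.df[name]

    def complete_rows(self, columns: Iterable[str]) -> pd.DataFrame:
        """Rows with non-missing values in all the given columns."""
        cols = list(columns)
        for c in cols:
            self.column(c)
        return self.df.dropna(subset=cols)


_NUMERIC_ROLES = {"descriptor", "property"}


def read_compound_table(
    path: str | Path,
    roles: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> CompoundTable:
    """Read a CSV/TSV compound table with a mandatory header row.

    ``roles`` maps column names to one of ``id``/``structure``/``formula``/
    ``descriptor``/``property``; columns with numeric roles are validated and
    non-numeric entries reported with their row number. Blank cells become
    missing values (NaN) with the row retained.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df = df.replace("", pd.NA)
    roles = dict(roles or {})
    id_col = next((c for c, r in roles.items() if r == "id"), "id")
    if id_col not in df.columns:
        raise TableError(f"missing mandatory id column {id_col!r} in {path}")
    if id_col != "id":
        df = df.rename(columns={id_col: "id"})
        roles["id"] = roles.pop(id_col)
    if df["id"].isna().any():
        rows = (df.index[df["id"].isna()] + 2).tolist()  # +2: header + 1-based
        raise TableError(f"missing id in row(s) {rows} of {path}")
    for col, role in roles.items():
        if role in _NUMERIC_ROLES and col not in df.columns:
            raise TableError(f"missing mandatory column {col!r} in {path}")
    for col in df.columns:
        role = roles.get(col)
        if role in ("id", "structure", "formula"):
            continue
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & numeric.isna()
        if role in _NUMERIC_ROLES and bad.any():
            row = int(bad.idxmax()) + 2
            raise TableError(f"non-numeric entry {df[col][bad.idxmax()]!r} in column {col!r}, row {row} of {path}")
        if role in _NUMERIC_ROLES or (not bad.any() and numeric.notna().any()):
            df[col] = numeric
    return CompoundTable(df=df, roles=roles)


def write_compound_table(table: CompoundTable, path: str | Path) -> None:
    """Write a compound table as UTF-8 CSV; missing values as empty cells."""
    table.df.to_csv(path, index=False, na_rep="")


def iter_molecules(table: CompoundTable, structure_col: str = "smiles") -> Iterator[Molecule]:
    """Yield validated molecules from a table's structure column."""
    col = table.column(structure_col)
    for mol_id, smi in zip(table.ids, col):
        if pd.isna(smi):
            continue
        yield mol_from_smiles(str(smi), mol_id)
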