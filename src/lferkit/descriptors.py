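"""Molecular descriptors for the partition-coefficient LFER.

Three descriptors drive the linear free energy relationship implemented by
this package:

* ``S_m`` — a molecular size descriptor computed from the molecular formula
  alone: a weighted sum of element counts with small negative corrections for
  branched sp3 carbons. Each element's weight reflects its relative
  contribution to the solute's effective size in nonpolar transfer processes.
* ``Flex`` — the sum of per-bond flexibility values over the solute's bonds.
  Bonds are scored categorically (0, 0.5, 1 or 1.5) by an ordered rule table
  keyed to rotational energy barriers and to whether rotation actually
  changes the heavy-atom conformation.
* ``H_M_HBD`` — the overall hydrogen-bond-donor capability of the solute on a
  transfer free-energy scale. Its rigorous computation belongs to a separate
  method; here it is pluggable data (a per-compound lookup table, or an
  approximate built-in fragment sum for convenience).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem
from sklearn.base import BaseEstimator, TransformerMixin

from .chemio import (
    CarbonEnvironmentCounts,
    MolecularFormula,
    Molecule,
    formula_from_mol,
    mol_from_smiles,
    perceive_carbon_environments,
)
from .errors import MissingDescriptor

logger = logging.getLogger(__name__)

#: Per-atom contributions to the size descriptor S_m.
SM_ELEMENT_WEIGHTS: dict[str, float] = {
    "C": 1.0,
    "H": 0.3,
    "O": 1.0,
    "N": 1.0,
    "S": 2.0,
    "F": 0.6,
    "Cl": 1.8,
    "Br": 2.2,
    "I": 2.6,
}
#: Correction per sp3 carbon with exactly three non-fluorine heavy neighbors.
SM_NC3_CORRECTION = -0.2
#: Correction per sp3 carbon with exactly four non-fluorine heavy neighbors.
SM_NC4_CORRECTION = -0.6


def sm_from_formula(
    formula: MolecularFormula,
    env: CarbonEnvironmentCounts | tuple[int, int] = (0, 0),
) -> float:
    """Size descriptor S_m from a molecular formula and branching counts.

    S_m = c + 0.3 h + o + n + 2 s + 0.6 f + 1.8 cl + 2.2 br + 2.6 i
          − 0.2 N_c3 − 0.6 N_c4

    where the lower-case letters are element counts and N_c3/N_c4 count sp3
    carbons bonded to exactly three/four non-fluorine heavy atoms. When only
    a formula is known the environment counts default to (0, 0).

    >>> sm_from_formula(parse_formula("C6H6O2"))   # catechol
    9.8
    """
    if isinstance(env, tuple):
        env = CarbonEnvironmentCounts(*env)
    total = sum(SM_ELEMENT_WEIGHTS[sym] * cnt for sym, cnt in formula.counts.items())
    total += SM_NC3_CORRECTION * env.n_c3 + SM_NC4_CORRECTION * env.n_c4
    return total


def sm_from_structure(mol: Molecule) -> float:
    """Size descriptor S_m computed from a parsed structure.

    Derives the formula (implicit hydrogens included) and the sp3-carbon
    branching environment from the structure, then applies
    :func:`sm_from_formula`.
    """
    return sm_from_formula(formula_from_mol(mol), perceive_carbon_environments(mol))


# ---------------------------------------------------------------------------
# Flex: rule-based bond flexibility
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BondFlexAssignment:
    """Audit record for one bond's flexibility value."""

    atoms: tuple[int, int]
    symbols: tuple[str, str]
    value: float
    rule_id: str


@dataclass(frozen=True)
class FlexRule:
    """One rule in the flexibility table.

    ``matcher`` is either a callable ``(bond, mol) -> bool`` or a two-atom
    SMARTS pattern; the first rule (in table order) whose matcher accepts the
    bond assigns its value.
    """

    rule_id: str
    value: float
    matcher: Callable[[Chem.Bond, Chem.Mol], bool] | str
    note: str = ""

    def matches(self, bond: Chem.Bond, rdmol: Chem.Mol) -> bool:
        if callable(self.matcher):
            return self.matcher(bond, rdmol)
        patt = Chem.MolFromSmarts(self.matcher)
        if patt is None:
            raise ValueError(f"invalid SMARTS in rule {self.rule_id!r}: {self.matcher!r}")
        pair = {bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()}
        return any(set(match[:2]) == pair for match in rdmol.GetSubstructMatches(patt))


def _heavy_neighbors(atom: Chem.Atom, exclude: Chem.Atom) -> list[Chem.Atom]:
    return [n for n in atom.GetNeighbors() if n.GetIdx() != exclude.GetIdx() and n.GetSymbol() != "H"]


def _end_rotation_trivial(atom: Chem.Atom, partner: Chem.Atom) -> bool:
    """True when rotating the bond permutes only hydrogens or symmetry-
    equivalent terminal substituents on ``atom``'s side (methyl, CX3 with
    identical terminal X, —OH, —NH2, terminal halogens)."""
    others = _heavy_neighbors(atom, partner)
    if not others:
        return True  # only hydrogens (or nothing) move
    if len(others) == 3:
        syms = {a.GetSymbol() for a in others}
        all_terminal = all(len(_heavy_neighbors(a, atom)) == 0 for a in others)
        if len(syms) == 1 and all_terminal and atom.GetTotalNumHs() == 0:
            return True  # three-fold symmetric top, e.g. CF3, C(CH3)3
    return False


def _is_symmetric_rotation(bond: Chem.Bond, rdmol: Chem.Mol) -> bool:
    a, b = bond.GetBeginAtom(), bond.GetEndAtom()
    return _end_rotation_trivial(a, b) or _end_rotation_trivial(b, a)


def _is_carbonyl_carbon(atom: Chem.Atom) -> bool:
    if atom.GetSymbol() != "C":
        return False
    return any(
        b.GetBondType() == Chem.BondType.DOUBLE and b.GetOtherAtom(atom).GetSymbol() == "O"
        for b in atom.GetBonds()
    )


def _is_amide_or_aryl_carbonyl(bond: Chem.Bond, rdmol: Chem.Mol) -> bool:
    a, b = bond.GetBeginAtom(), bond.GetEndAtom()
    for x, y in ((a, b), (b, a)):
        if _is_carbonyl_carbon(x) and y.GetSymbol() == "N":
            return True  # amide C–N: partial double-bond character
        if _is_carbonyl_carbon(x) and y.GetIsAromatic() and y.GetSymbol() == "C":
            return True  # aryl–carbonyl conjugation
    return False


def _is_ether_alkyl(bond: Chem.Bond, rdmol: Chem.Mol) -> bool:
    a, b = bond.GetBeginAtom(), bond.GetEndAtom()
    for x, y in ((a, b), (b, a)):
        if (
            x.GetSymbol() == "C"
            and x.GetHybridization() == Chem.HybridizationType.SP3
            and y.GetSymbol() == "O"
            and len([n for n in y.GetNeighbors() if n.GetSymbol() != "H"]) >= 2
        ):
            return True
    return False


def _is_benzylic(bond: Chem.Bond, rdmol: Chem.Mol) -> bool:
    a, b = bond.GetBeginAtom(), bond.GetEndAtom()
    for x, y in ((a, b), (b, a)):
        if (
            x.GetSymbol() == "C"
            and x.GetHybridization() == Chem.HybridizationType.SP3
            and y.GetIsAromatic()
            and y.GetSymbol() == "C"
        ):
            return True
    return False


def _is_conjugated_sp2_pair(bond: Chem.Bond, rdmol: Chem.Mol) -> bool:
    def sp2ish(atom: Chem.Atom) -> bool:
        return atom.GetIsAromatic() or atom.GetHybridization() == Chem.HybridizationType.SP2

    return sp2ish(bond.GetBeginAtom()) and sp2ish(bond.GetEndAtom())


DEFAULT_FLEX_RULES: tuple[FlexRule, ...] = (
    FlexRule(
        "symmetric_rotation", 0.0, _is_symmetric_rotation,
        "rotation permutes only hydrogens or symmetry-equivalent terminal atoms",
    ),
    FlexRule(
        "amide_or_aryl_carbonyl", 0.0, _is_amide_or_aryl_carbonyl,
        "rotation barrier well above the CH2–CH2 reference (conjugation)",
    ),
    FlexRule(
        "ether_alkyl", 1.5, _is_ether_alkyl,
        "rotation barrier well below the CH2–CH2 reference",
    ),
    FlexRule(
        "benzylic", 0.5, _is_benzylic,
        "phenyl two-fold symmetry halves the distinguishable conformations",
    ),
    FlexRule(
        "conjugated_sp2", 0.0, _is_conjugated_sp2_pair,
        "single bond between two sp2 centres; conjugation raises the barrier",
    ),
    FlexRule("default", 1.0, lambda bond, mol: True, "acyclic single bond between heavy atoms"),
)


@dataclass
class FlexRuleTable:
    """Ordered flexibility rules; first match wins, last rule must be a
    catch-all so every rotatable bond is assigned."""

    rules: Sequence[FlexRule] = DEFAULT_FLEX_RULES

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("rule table must not be empty")
        # A terminal catch-all is required so every bond gets an assignment.
        if self.rules[-1].rule_id != "default":
            raise ValueError("rule table must end with a terminal 'default' rule")

    def assign(self, bond: Chem.Bond, rdmol: Chem.Mol) -> tuple[float, str]:
        for rule in self.rules:
            try:
                hit = rule.matches(bond, rdmol)
            except Exception:
                logger.warning("flex rule %s failed on bond %d-%d; skipping",
                               rule.rule_id, bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
                continue
            if hit:
                return rule.value, rule.rule_id
        # unreachable when the terminal default is present
        warnings.warn("no flex rule matched; assigning default 1.0", stacklevel=2)
        return 1.0, "default"


def load_flex_rules(path: str | Path) -> FlexRuleTable:
    """Load user flexibility rules from a plain-text file.

    Each non-comment line is ``rule_id  SMARTS  value`` (whitespace
    separated); rules apply in file order, before the built-in terminal
    default of 1.0. Ring and multiple bonds are always non-rotatable and are
    excluded before any rule runs.
    """
    rules: list[FlexRule] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 'rule_id SMARTS value', got {line!r}")
        rules.append(FlexRule(parts[0], float(parts[2]), parts[1]))
    rules.append(DEFAULT_FLEX_RULES[-1])
    return FlexRuleTable(tuple(rules))


def flex_from_structure(
    mol: Molecule, rules: FlexRuleTable | None = None
) -> tuple[float, list[BondFlexAssignment]]:
    """Total flexibility of a solute and the per-bond audit trail.

    Every bond between heavy atoms receives an assignment. Ring bonds and
    double/triple/aromatic bonds are non-rotatable and scored 0 without rule
    lookup; the remaining acyclic single bonds are scored by the first
    matching rule of ``rules`` (default table if omitted). The total is the
    sum of the emitted per-bond values.
    """
    if rules is None:
        rules = FlexRuleTable()
    rdmol = mol.rdmol
    assignments: list[BondFlexAssignment] = []
    for bond in rdmol.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetSymbol() == "H" or b.GetSymbol() == "H":
            continue
        pair = (a.GetIdx(), b.GetIdx())
        syms = (a.GetSymbol(), b.GetSymbol())
        if bond.IsInRing() or bond.GetBondType() != Chem.BondType.SINGLE:
            assignments.append(BondFlexAssignment(pair, syms, 0.0, "non_rotatable"))
            continue
        value, rule_id = rules.assign(bond, rdmol)
        assignments.append(BondFlexAssignment(pair, syms, value, rule_id))
    total = float(sum(a.value for a in assignments))
    return total, assignments


# ---------------------------------------------------------------------------
# H_M_HBD providers
# ---------------------------------------------------------------------------

class TableHMHBDProvider:
    """Provider (a): per-compound H_M_HBD lookup from user-supplied data."""

    def __init__(self, values: Mapping[str, float]) -> None:
        self._values = {str(k): float(v) for k, v in values.items()}

    def __call__(self, mol_or_id: Molecule | str) -> float:
        key = mol_or_id.id if isinstance(mol_or_id, Molecule) else str(mol_or_id)
        if key not in self._values:
            raise MissingDescriptor(key, "HM_HBD")
        return self._values[key]


#: Approximate donor-group contributions on the transfer free-energy scale.
#: Synthetic stand-in values (order matters: more specific patterns first);
#: a rigorous H_M_HBD comes from user-supplied data via TableHMHBDProvider.
DEFAULT_HBD_FRAGMENTS: tuple[tuple[str, str, float], ...] = (
    ("carboxylic_acid_OH", "[CX3](=O)[OX2H1]", 3.5),
    ("phenol_OH", "[OX2H1]c", 3.0),
    ("alcohol_OH", "[OX2H1][CX4]", 2.5),
    ("amide_NH", "[NX3;H1,H2][CX3]=[OX1]", 2.0),
    ("amine_NH", "[NX3;H1,H2,H3]", 1.5),
    ("thiol_SH", "[SX2H1]", 0.5),
    ("polyhalo_CH", "[CX4H1]([F,Cl,Br,I])([F,Cl,Br,I])[F,Cl,Br,I]", 0.3),
)


class FragmentHMHBDProvider:
    """Provider (b): approximate fragment-contribution estimate of H_M_HBD.

    Sums per-donor-group contributions over SMARTS matches, counting each
    donor heteroatom once (first matching pattern wins). The built-in table
    is an approximate synthetic stand-in on the right free-energy scale, not
    a reproduction of any published scheme; compounds with no donor groups
    return 0.
    """

    def __init__(self, fragments: Iterable[tuple[str, str, float]] = DEFAULT_HBD_FRAGMENTS) -> None:
        self.fragments = [(fid, Chem.MolFromSmarts(s), val) for fid, s, val in fragments]
        for fid, patt, _ in self.fragments:
            if patt is None:
                raise ValueError(f"invalid SMARTS in fragment {fid!r}")

    def __call__(self, mol_or_id: Molecule | str) -> float:
        if not isinstance(mol_or_id, Molecule):
            mol_or_id = mol_from_smiles(str(mol_or_id))
        rdmol = mol_or_id.rdmol
        claimed: set[int] = set()
        total = 0.0
        for _fid, patt, value in self.fragments:
            for match in rdmol.GetSubstructMatches(patt):
                donor = match[0]
                if donor in claimed:
                    continue
                claimed.add(donor)
                n_h = rdmol.GetAtomWithIdx(donor).GetTotalNumHs()
                total += value * max(n_h, 1)
        return total


# ---------------------------------------------------------------------------
# Descriptor vector and sklearn transformer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DescriptorVector:
    """Per-compound predictor values for the LFER.

    ``basis_name`` records which partition-coefficient scale ``logp_basis``
    is on ("logP16", "logPoct" or "other"); prediction checks it against the
    model's basis.
    """

    s_m: float
    flex: float = 0.0
    h_m_hbd: float = 0.0
    logp_basis: float = 0.0
    basis_name: str = "other"

    def __post_init__(self) -> None:
        if self.flex < 0:
            raise ValueError("Flex must be non-negative")
        if self.basis_name not in ("logP16", "logPoct", "other"):
            raise ValueError(f"unknown basis name {self.basis_name!r}")

    def as_mapping(self) -> dict[str, float]:
        out = {"Sm": self.s_m, "Flex": self.flex, "HM_HBD": self.h_m_hbd}
        if self.basis_name != "other":
            out[self.basis_name] = self.logp_basis
        return out


class DescriptorCalculator(TransformerMixin, BaseEstimator):
    """Compute Sm/Flex (and optionally HM_HBD) columns from structures.

    A stateless sklearn transformer: ``transform`` accepts an iterable of
    SMILES strings or :class:`Molecule` objects and returns a DataFrame with
    columns ``Sm``, ``Flex`` and, when an ``hmhbd_provider`` is configured,
    ``HM_HBD``. Composes with sklearn pipelines feeding an LFER regressor.
    """

    def __init__(self, hmhbd_provider=None, flex_rules: FlexRuleTable | None = None) -> None:
        self.hmhbd_provider = hmhbd_provider
        self.flex_rules = flex_rules

    def fit(self, X, y=None):  # noqa: D102 - nothing to learn
        return self

    def transform(self, X) -> pd.DataFrame:
        mols = [x if isinstance(x, Molecule) else mol_from_smiles(str(x)) for x in X]
        rows = []
        for mol in mols:
            row = {
                "id": mol.id,
                "Sm": sm_from_structure(mol),
                "Flex": flex_from_structure(mol, self.flex_rules)[0],
            }
            if self.hmhbd_provider is not None:
                row["HM_HBD"] = self.hmhbd_provider(mol)
            rows.append(row)
        return pd.DataFrame(rows).set_index("id")


def compute_descriptors(
    mols: Iterable[Molecule | str],
    hmhbd_provider=None,
    flex_rules: FlexRuleTable | None = None,
) -> pd.DataFrame:
    """Functional wrapper over :class:`DescriptorCalculator`."""
    return DescriptorCalculator(hmhbd_provider, flex_rules).transform(mols)
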