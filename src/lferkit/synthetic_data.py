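"""Synthetic compound tables with known LFER structure, plus hand-verified
structure fixtures.

The generator emulates the statistical structure the LFER assumes: descriptor
columns drawn independently (optionally with a user-specified correlation via
a Gaussian copula) from realistic ranges, and a property column that is a
known linear combination of them plus Gaussian noise. It produces numerical
descriptor tables, not chemical structures — structures come from the small
fixture set whose descriptor values were verified by hand.

Defaults mirror the skin-permeability study design: the published
coefficient vector for logKp on (logPoct, Sm, HM_HBD, Flex), residual noise
of 0.18 log units, and a 32-compound training-set size.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .chemio import CompoundTable, Molecule, mol_from_smiles, parse_formula
from .lfer import get_preset

#: Default uniform sampling ranges for each descriptor column.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "logPoct": (-2.0, 6.0),
    "logP16": (-2.0, 6.0),
    "Sm": (2.0, 25.0),
    "HM_HBD": (0.0, 8.0),
    "Flex": (0.0, 6.0),  # snapped to the 0.5 grid the rule table produces
}

_DEFAULT_PRESET = "logKp/logPoct"


def _default_coefficients() -> dict[str, float]:
    return dict(get_preset(_DEFAULT_PRESET).coefficients)


@dataclass
class GeneratorSpec:
    """Recipe for one synthetic compound table.

    The same spec and seed always produce a byte-identical table. ``flex_grid``
    controls snapping of the Flex column to categorical half-unit values.
    """

    n: int = 32
    true_coefficients: Mapping[str, float] = field(default_factory=_default_coefficients)
    intercept: float = get_preset(_DEFAULT_PRESET).intercept
    property_name: str = "logKp"
    descriptor_ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    noise_sd: float = 0.18
    seed: int = 0
    correlation: np.ndarray | None = None
    flex_grid: float = 0.5

    def ranges(self) -> dict[str, tuple[float, float]]:
        out = {}
        for col in self.true_coefficients:
            lo, hi = self.descriptor_ranges.get(col, DEFAULT_RANGES.get(col, (0.0, 1.0)))
            if lo > hi:
                raise ValueError(f"degenerate range for {col!r}: ({lo}, {hi})")
            out[col] = (float(lo), float(hi))
        return out


def generate_table(spec: GeneratorSpec) -> CompoundTable:
    """Sample a compound table from a known LFER plus Gaussian noise.

    Descriptors are uniform over their ranges (independently, or coupled via
    a Gaussian copula when ``spec.correlation`` is given); the property is
    the specified linear combination plus N(0, noise_sd) noise. Generation
    metadata (true coefficients, intercept, noise draws) is stored on the
    table's ``meta`` for truth-recovery tests.
    """
    if spec.n < 1:
        raise ValueError("n must be at least 1")
    if spec.noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(spec.seed)
    ranges = spec.ranges()
    cols = list(ranges)
    k = len(cols)
    if spec.correlation is not None:
        corr = np.asarray(spec.correlation, dtype=float)
        if corr.shape != (k, k):
            raise ValueError(f"correlation matrix must be {k}x{k} for descriptors {cols}")
        chol = np.linalg.cholesky(corr)  # raises for non-PD input
        z = rng.standard_normal((spec.n, k)) @ chol.T
        u = sps.norm.cdf(z)
    else:
        u = rng.random((spec.n, k))
    data: dict[str, np.ndarray] = {}
    for j, col in enumerate(cols):
        lo, hi = ranges[col]
        x = lo + u[:, j] * (hi - lo)
        if col == "Flex" and spec.flex_grid > 0:
            x = np.round(x / spec.flex_grid) * spec.flex_grid
        data[col] = x
    noise = rng.normal(0.0, spec.noise_sd, size=spec.n) if spec.noise_sd > 0 else np.zeros(spec.n)
    y = spec.intercept + sum(spec.true_coefficients[c] * data[c] for c in cols) + noise
    if spec.noise_sd > 0 and abs(noise.mean()) > 3 * spec.noise_sd / np.sqrt(spec.n):
        warnings.warn("noise sample mean beyond 3 sd/sqrt(n); unusual draw", stacklevel=2)
    df = pd.DataFrame({"id": [f"synth{i + 1:04d}" for i in range(spec.n)], **data,
                       spec.property_name: y})
    roles = {c: "descriptor" for c in cols}
    roles[spec.property_name] = "property"
    roles["id"] = "id"
    meta = {
        "true_coefficients": dict(spec.true_coefficients),
        "intercept": spec.intercept,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "noise": noise,
    }
    return CompoundTable(df=df, roles=roles, meta=meta)


@dataclass(frozen=True)
class MoleculeFixture:
    """A structure with hand-verified descriptor values."""

    id: str
    smiles: str
    formula: str
    sm: float
    flex: float
    n_c3: int
    n_c4: int

    @property
    def molecule(self) -> Molecule:
        return mol_from_smiles(self.smiles, self.id)


def fixture_records() -> list[MoleculeFixture]:
    """The packaged fixture set: ~30 structures (alkanes, aromatics, ethers,
    amides, esters, halogenated and H-bonding compounds) whose S_m, Flex and
    (N_c3, N_c4) values were tallied by hand."""
    text = resources.files("lferkit.data").joinpath("fixture_molecules.csv").read_text()
    out: list[MoleculeFixture] = []
    for row in csv.DictReader(text.splitlines()):
        parse_formula(row["formula"])  # sanity: fixture formulas are well-formed
        out.append(MoleculeFixture(
            id=row["id"], smiles=row["smiles"], formula=row["formula"],
            sm=float(row["sm"]), flex=float(row["flex"]),
            n_c3=int(row["n_c3"]), n_c4=int(row["n_c4"]),
        ))
    return out


def generate_molecule_fixtures() -> list[Molecule]:
    """Parsed molecules for the packaged fixture set."""
    return [f.molecule for f in fixture_records()]
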