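"""Physicochemical descriptors of the fluoroquinolone set.

Three descriptors drive the downstream structure-property analysis:

* monoisotopic molecular weight (sum of most-abundant-isotope masses,
  hydrogens included),
* topological polar surface area (TPSA) by the Ertl fragment-contribution
  method, counting N, O, S and P environments as polar,
* logP by the Wildman-Crippen atomic-contribution model.

All three are computed with RDKit.  Aromaticity perception matters for
TPSA and logP on the 4-oxo-quinoline core: under RDKit's default model
both rings of the bicycle are perceived aromatic, which is the convention
this package fixes as its default (``quinolonoid_aromatic``).  The MDL
model, which leaves the pyridinone ring non-aromatic, is selectable as
``kekule_pyridinone`` for sensitivity checks.

Descriptors are computed on the neutral, as-drawn structures; the
energetics stage models the N-protonated cation separately.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Literal

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from .errors import ParseError

__all__ = [
    "AromaticityConvention",
    "MoleculeRecord",
    "parse_smiles",
    "monoisotopic_mass",
    "average_mass",
    "tpsa",
    "crippen_logp",
    "compute_descriptors",
    "load_fq_smiles",
    "load_table1_reference",
    "descriptor_table",
]

AromaticityConvention = Literal["quinolonoid_aromatic", "kekule_pyridinone"]

DEFAULT_CONVENTION: AromaticityConvention = "quinolonoid_aromatic"

#: polar elements of the TPSA sum; S and P contributions are switched on
#: to match the N/O/S/P-polar flavour of the Ertl method
POLAR_ELEMENTS = frozenset({"N", "O", "S", "P"})


def parse_smiles(
    smiles: str, convention: AromaticityConvention = DEFAULT_CONVENTION
) -> Chem.Mol:
    """Parse a SMILES string under the package aromaticity convention."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    if convention == "kekule_pyridinone":
        Chem.Kekulize(mol, clearAromaticFlags=True)
        Chem.SetAromaticity(mol, Chem.AromaticityModel.AROMATICITY_MDL)
    elif convention != "quinolonoid_aromatic":
        raise ParseError(f"unknown aromaticity convention {convention!r}")
    return mol


def monoisotopic_mass(smiles: str) -> float:
    """Monoisotopic molecular weight in g/mol (hydrogens included)."""
    return float(Descriptors.ExactMolWt(parse_smiles(smiles)))


def average_mass(smiles: str) -> float:
    """Average (isotope-abundance-weighted) molecular weight in g/mol.

    Exposed under a distinct name: the packaged reference table uses
    monoisotopic masses, and conflating the two is a classic source of
    0.1-1 g/mol discrepancies.
    """
    return float(Descriptors.MolWt(parse_smiles(smiles)))


def tpsa(
    smiles: str,
    polar_elements: frozenset[str] = POLAR_ELEMENTS,
    convention: AromaticityConvention = DEFAULT_CONVENTION,
) -> float:
    """Ertl topological polar surface area in square Angstroms."""
    include_sp = bool(polar_elements & {"S", "P"})
    if polar_elements - {"N", "O", "S", "P"}:
        raise ParseError(f"unsupported polar elements: {polar_elements}")
    mol = parse_smiles(smiles, convention)
    return float(rdMolDescriptors.CalcTPSA(mol, includeSandP=include_sp))


def crippen_logp(
    smiles: str, convention: AromaticityConvention = DEFAULT_CONVENTION
) -> float:
    """Wildman-Crippen logP (atomic contributions, hydrogens included)."""
    return float(Crippen.MolLogP(parse_smiles(smiles, convention)))


@dataclass
class MoleculeRecord:
    """One fluoroquinolone with its identity and computed descriptors."""

    name: str
    generation: Literal["second", "third", "fourth"]
    smiles: str
    formula: str = ""
    mw: float = 0.0     # monoisotopic, g/mol
    tpsa: float = 0.0   # A^2
    logp: float = 0.0

    @classmethod
    def from_smiles(
        cls,
        name: str,
        generation: str,
        smiles: str,
        convention: AromaticityConvention = DEFAULT_CONVENTION,
    ) -> "MoleculeRecord":
        mol = parse_smiles(smiles, convention)
        if len(Chem.GetMolFrags(mol)) != 1:
            raise ParseError(f"{name}: SMILES encodes a disconnected structure")
        return cls(
            name=name,
            generation=generation,  # type: ignore[arg-type]
            smiles=smiles,
            formula=rdMolDescriptors.CalcMolFormula(mol),
            mw=monoisotopic_mass(smiles),
            tpsa=tpsa(smiles, convention=convention),
            logp=crippen_logp(smiles, convention=convention),
        )


def compute_descriptors(
    smiles: str, convention: AromaticityConvention = DEFAULT_CONVENTION
) -> dict[str, float]:
    """All three descriptors for one structure as a plain dict."""
    return {
        "mw": monoisotopic_mass(smiles),
        "tpsa": tpsa(smiles, convention=convention),
        "logp": crippen_logp(smiles, convention=convention),
    }


def _data_path(name: str):
    return resources.files("fqchelate.data").joinpath(name)


def load_fq_smiles() -> list[tuple[str, str, str]]:
    """The packaged (name, generation, SMILES) fixture, one row per drug."""
    rows = []
    with _data_path("fq_smiles.tsv").open("r") as fh:
        for record in csv.reader(fh, delimiter="\t"):
            if record:
                rows.append((record[0], record[1], record[2]))
    return rows


def load_table1_reference() -> pd.DataFrame:
    """Packaged reference descriptor table (name, generation, mw, tpsa, logp)."""
    with _data_path("table1_reference.csv").open("r") as fh:
        return pd.read_csv(fh)


def descriptor_table(
    convention: AromaticityConvention = DEFAULT_CONVENTION,
) -> list[MoleculeRecord]:
    """Descriptors computed from the packaged SMILES fixture for all drugs."""
    return [
        MoleculeRecord.from_smiles(name, gen, smi, convention)
        for name, gen, smi in load_fq_smiles()
    ]


def descriptor_frame(
    convention: AromaticityConvention = DEFAULT_CONVENTION,
) -> pd.DataFrame:
    """Same as :func:`descriptor_table` but as a DataFrame for CSV export."""
    recs = descriptor_table(convention)
    return pd.DataFrame(
        {
            "name": [r.name for r in recs],
            "generation": [r.generation for r in recs],
            "formula": [r.formula for r in recs],
            "mw": [r.mw for r in recs],
            "tpsa": [r.tpsa for r in recs],
            "logp": [r.logp for r in recs],
        }
    )
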