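"""Molecule parsing, canonicalization, descriptors, fingerprints and .smi I/O.

Every downstream stage (corpus curation, drug-likeness scoring, scaffold
analysis, affinity ranking) works on :class:`MoleculeRecord` objects produced
here, so identity and validity semantics are defined once:

* a SMILES is *valid* iff RDKit can parse **and** sanitize it (standard
  valence rules); parse failure and sanitization failure are treated
  identically,
* molecular identity is the RDKit canonical SMILES, used for deduplication
  everywhere.

The eight-component descriptor vector is the classic QED descriptor set
(MW, ALOGP, HBA, HBD, PSA, ROTB, AROM, ALERTS).  Definitions follow the
published QED parameterization shipped in ``data/qed_params.json``: hydrogen
bond acceptors are counted by the acceptor SMARTS set (total substructure
matches), ALERTS counts how many structural-alert patterns match at least
once (not matches per pattern), and aromatic-ring counting removes aliphatic
rings first so fused aromatic systems are counted by SSSR.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, DataStructs, MolSurf, rdFingerprintGenerator
from rdkit.Chem import rdMolDescriptors as rdmd

RDLogger.DisableLog("rdApp.*")

log = logging.getLogger(__name__)

DESCRIPTOR_NAMES = ("MW", "ALOGP", "HBA", "HBD", "PSA", "ROTB", "AROM", "ALERTS")

#: aliphatic ring atoms bonded to a non-aromatic neighbour; deleted before
#: counting aromatic rings so e.g. tetralin counts one aromatic ring
_ALIPHATIC_RINGS = Chem.MolFromSmarts("[$([A;R][!a])]")


@dataclass(frozen=True)
class MoleculeRecord:
    """A parsed molecule; ``canonical_smiles`` is present iff ``valid``."""

    raw_smiles: str
    canonical_smiles: str | None = None
    name: str | None = None
    valid: bool = False

    def mol(self) -> Chem.Mol:
        if not self.valid:
            raise ValueError(f"invalid molecule: {self.raw_smiles!r}")
        return Chem.MolFromSmiles(self.canonical_smiles)


@dataclass(frozen=True)
class DescriptorVector:
    """QED descriptor set: MW g/mol, ALOGP, HBA/HBD counts, PSA Å², ROTB,
    aromatic-ring count and structural-alert count."""

    MW: float
    ALOGP: float
    HBA: int
    HBD: int
    PSA: float
    ROTB: int
    AROM: int
    ALERTS: int

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in DESCRIPTOR_NAMES}


@dataclass(frozen=True)
class Fingerprint:
    """Hashed Morgan (circular) fingerprint."""

    bits: "DataStructs.ExplicitBitVect"
    radius: int
    nbits: int


def _load_qed_table() -> dict:
    with resources.files("denovotki.data").joinpath("qed_params.json").open() as fh:
        return json.load(fh)


_QED_TABLE = _load_qed_table()
_ACCEPTORS = [Chem.MolFromSmarts(s) for s in _QED_TABLE["acceptor_smarts"]]
_ALERTS = [Chem.MolFromSmarts(s) for s in _QED_TABLE["alert_smarts"]]


def parse_and_canonicalize(smiles: str, name: str | None = None) -> MoleculeRecord:
    """Parse a SMILES string; invalidity is a data state, never an exception.

    Canonicalization is a fixed point: feeding back ``canonical_smiles``
    returns the same string.
    """
    if not isinstance(smiles, str) or not smiles:
        raise ValueError("smiles must be a non-empty string")
    mol = Chem.MolFromSmiles(smiles)  # parses + sanitizes
    if mol is None:
        return MoleculeRecord(raw_smiles=smiles, name=name, valid=False)
    return MoleculeRecord(
        raw_smiles=smiles,
        canonical_smiles=Chem.MolToSmiles(mol),
        name=name,
        valid=True,
    )


def compute_descriptors(record: MoleculeRecord) -> DescriptorVector:
    """Compute the eight QED descriptors for a valid molecule."""
    mol = Chem.RemoveHs(record.mol())
    hba = sum(
        len(mol.GetSubstructMatches(p)) for p in _ACCEPTORS if mol.HasSubstructMatch(p)
    )
    arom = len(Chem.GetSSSR(Chem.DeleteSubstructs(Chem.Mol(mol), _ALIPHATIC_RINGS)))
    return DescriptorVector(
        MW=rdmd._CalcMolWt(mol),
        ALOGP=Crippen.MolLogP(mol),
        HBA=hba,
        HBD=rdmd.CalcNumHBD(mol),
        PSA=MolSurf.TPSA(mol),
        ROTB=rdmd.CalcNumRotatableBonds(mol, rdmd.NumRotatableBondsOptions.Strict),
        AROM=arom,
        ALERTS=sum(1 for a in _ALERTS if mol.HasSubstructMatch(a)),
    )


def morgan_fingerprint(
    record: MoleculeRecord, radius: int = 2, nbits: int = 2048
) -> Fingerprint:
    """Hashed Morgan fingerprint; invariant to the SMILES writing order."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if nbits <= 0 or nbits & (nbits - 1):
        raise ValueError("nbits must be a positive power of two")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    return Fingerprint(bits=gen.GetFingerprint(record.mol()), radius=radius, nbits=nbits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    if (a.radius, a.nbits) != (b.radius, b.nbits):
        raise ValueError("fingerprints have different parameters")
    return DataStructs.TanimotoSimilarity(a.bits, b.bits)


def read_smi(path: str | Path) -> list[MoleculeRecord]:
    """Read a SMILES-per-line file, optional tab-separated name column.

    Blank lines are skipped (count logged); malformed SMILES come back as
    records with ``valid=False``.
    """
    records: list[MoleculeRecord] = []
    blank = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                blank += 1
                continue
            smiles, _, name = line.partition("\t")
            records.append(parse_and_canonicalize(smiles.strip(), name=name.strip() or None))
    if blank:
        log.info("read_smi(%s): skipped %d blank line(s)", path, blank)
    return records


def write_smi(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    """Write records as ``SMILES[<TAB>name]``; canonical form when available."""
    with open(path, "w") as fh:
        for rec in records:
            smiles = rec.canonical_smiles if rec.valid else rec.raw_smiles
            fh.write(smiles + (f"\t{rec.name}" if rec.name else "") + "\n")


def descriptor_table(records: Sequence[MoleculeRecord]):
    """CSV-ready descriptor table, one row per valid molecule.

    Header fixed: smiles,name,MW,ALOGP,HBA,HBD,PSA,ROTB,AROM,ALERTS.
    """
    import pandas as pd

    rows = []
    for rec in records:
        if not rec.valid:
            continue
        row = {"smiles": rec.canonical_smiles, "name": rec.name}
        row.update(compute_descriptors(rec).as_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=["smiles", "name", *DESCRIPTOR_NAMES])
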