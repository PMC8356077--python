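"""Murcko scaffolds, cyclic skeletons (CSK) and ring-topology analysis.

A Murcko scaffold is a molecule's ring systems plus the linkers connecting
them, with side chains removed.  The cyclic skeleton abstracts the scaffold
one step further: every heavy atom becomes carbon and every bond a single
bond, so pyridine and benzene collapse to the same skeleton.  Grouping
skeletons by ring count, and classifying two-ring skeletons by how their
rings share atoms (linked / spiro / fused / bridged), summarizes the core
structural diversity of a compound set.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .chemio import MoleculeRecord, parse_and_canonicalize

BicyclicClass = Literal["fused", "bridged", "spiro", "linked", "not_bicyclic"]


@dataclass(frozen=True)
class ScaffoldRecord:
    source_canonical: str
    scaffold_smiles: str | None
    csk_smiles: str | None
    ring_count: int
    bicyclic_class: BicyclicClass


def murcko_scaffold(record: MoleculeRecord) -> str | None:
    """Ring systems + linkers, side chains removed; None for acyclic input."""
    mol = record.mol()
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return None
    return Chem.MolToSmiles(scaffold)


def csk(scaffold_smiles: str) -> str:
    """Cyclic skeleton: all heavy atoms -> C, all bonds -> single, charges,
    stereo and aromaticity cleared; canonicalized. Idempotent."""
    mol = Chem.MolFromSmiles(scaffold_smiles)
    if mol is None:
        raise ValueError(f"invalid scaffold SMILES: {scaffold_smiles!r}")
    skel = Chem.RWMol(mol)
    for atom in skel.GetAtoms():
        atom.SetAtomicNum(6)
        atom.SetFormalCharge(0)
        atom.SetIsAromatic(False)
        atom.SetNoImplicit(False)
        atom.SetNumExplicitHs(0)
        atom.SetChiralTag(Chem.ChiralType.CHI_UNSPECIFIED)
    for bond in skel.GetBonds():
        bond.SetBondType(Chem.BondType.SINGLE)
        bond.SetIsAromatic(False)
        bond.SetStereo(Chem.BondStereo.STEREONONE)
    out = skel.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def _ring_atom_sets(smiles: str) -> list[frozenset[int]]:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    return [frozenset(r) for r in Chem.GetSymmSSSR(mol)]


def _pair_class(a: frozenset[int], b: frozenset[int]) -> BicyclicClass:
    shared = len(a & b)
    if shared == 0:
        return "linked"
    if shared == 1:
        return "spiro"
    if shared == 2:
        return "fused"
    return "bridged"


def classify_bicyclic(csk_smiles: str) -> BicyclicClass:
    """Classify a two-ring skeleton by SSSR ring-atom sharing:
    0 shared atoms -> linked, 1 -> spiro, 2 -> fused, >2 -> bridged.
    Skeletons without exactly two SSSR rings are ``not_bicyclic``."""
    rings = _ring_atom_sets(csk_smiles)
    if len(rings) != 2:
        return "not_bicyclic"
    return _pair_class(rings[0], rings[1])


def ring_pair_classes(csk_smiles: str) -> set[BicyclicClass]:
    """Containment view for multi-ring skeletons: the set of pair classes
    over every SSSR ring pair (a tricyclic molecule can simultaneously
    'contain a fused pair' and 'contain a bridged pair')."""
    rings = _ring_atom_sets(csk_smiles)
    return {_pair_class(a, b) for a, b in combinations(rings, 2)}


def scaffold_record(record: MoleculeRecord) -> ScaffoldRecord:
    scaffold = murcko_scaffold(record)
    if scaffold is None:
        return ScaffoldRecord(record.canonical_smiles, None, None, 0, "not_bicyclic")
    skeleton = csk(scaffold)
    rings = _ring_atom_sets(skeleton)
    return ScaffoldRecord(
        source_canonical=record.canonical_smiles,
        scaffold_smiles=scaffold,
        csk_smiles=skeleton,
        ring_count=len(rings),
        bicyclic_class=classify_bicyclic(skeleton),
    )


def csk_hierarchy(records: Sequence[ScaffoldRecord]) -> pd.DataFrame:
    """Layered frequency table: layer = ring count (0 = acyclic bucket);
    within a layer, skeletons ranked by descending count, ties broken
    lexicographically. Counts over all layers sum to the input size."""
    counter: Counter[tuple[int, str | None]] = Counter()
    example: dict[tuple[int, str | None], str] = {}
    for rec in records:
        key = (rec.ring_count, rec.csk_smiles)
        counter[key] += 1
        example.setdefault(key, rec.source_canonical)
    rows = [
        {
            "layer": layer,
            "csk_smiles": skel,
            "count": n,
            "example_source": example[(layer, skel)],
        }
        for (layer, skel), n in counter.items()
    ]
    df = pd.DataFrame(rows, columns=["layer", "csk_smiles", "count", "example_source"])
    if len(df):
        df = df.sort_values(
            ["layer", "count", "csk_smiles"],
            ascending=[True, False, True],
            na_position="first",
        ).reset_index(drop=True)
    return df


def containment_counts(records: Sequence[ScaffoldRecord]) -> dict[str, int]:
    """Per-molecule containment counts over ring pairs: how many molecules
    contain at least one fused / bridged / spiro / linked ring pair."""
    counts = {"fused": 0, "bridged": 0, "spiro": 0, "linked": 0}
    for rec in records:
        if rec.csk_smiles is None or rec.ring_count < 2:
            continue
        for cls in ring_pair_classes(rec.csk_smiles):
            counts[cls] += 1
    return counts


def analyze(smiles_list: Sequence[str]) -> list[ScaffoldRecord]:
    """Scaffold records for every valid SMILES in a list (invalid skipped)."""
    out = []
    for s in smiles_list:
        rec = parse_and_canonicalize(s)
        if rec.valid:
            out.append(scaffold_record(rec))
    return out
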