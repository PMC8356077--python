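"""Drug-likeness scoring and physicochemical filtering.

Three scores are implemented:

* **ADS desirability** — the asymmetric double sigmoidal curve

  .. math::

     D(x) = a + \\frac{b}{1 + e^{-(x - c + d/2)/e}}
            \\Bigl[1 - \\frac{1}{1 + e^{-(x - c - d/2)/f}}\\Bigr]

  mapping one descriptor value to a desirability; the published
  parameterization (per-descriptor a..f, a normalization maximum, and
  weights) ships in ``data/qed_params.json``.

* **QED** — the weighted geometric mean of the eight normalized
  desirabilities, ``exp(Σ w_i ln d_i / Σ w_i)``, in (0, 1].

* **SA score** — synthetic accessibility as fragment score minus complexity
  penalty, rescaled to [1, 10] (lower = easier to make).  The fragment
  contribution table is a frequency analysis of circular fragments over a
  large compound collection; by default it is loaded from the RDKit Contrib
  distribution at run time, and :func:`fragment_contributions_from_corpus`
  can rebuild a table from any user corpus.

The hard filter applies the classic kinase-inhibitor screening window:
300 <= MW <= 700, 2 <= LogP <= 6, 2 <= HBD <= 6, HBA <= 12, HBA+HBD <= 14,
60 <= TPSA <= 140, rotatable bonds <= 12 (all bounds inclusive, all
configurable).  The HBD lower bound of 2 is intentional and can be relaxed
via a custom :class:`FilterCriteria`.
"""

from __future__ import annotations

import gzip
import json
import math
import os
import pickle
from collections import Counter, defaultdict
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors as rdmd

from .chemio import (
    DESCRIPTOR_NAMES,
    DescriptorVector,
    MoleculeRecord,
    compute_descriptors,
    parse_and_canonicalize,
)


# --------------------------------------------------------------------------
# ADS desirability and QED
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ADSParams:
    a: float
    b: float
    c: float
    d: float
    e: float
    f: float
    dmax: float = 1.0  # normalization constant: max of the raw curve

    def __post_init__(self) -> None:
        if self.e <= 0 or self.f <= 0:
            raise ValueError("ADS slope scales e and f must be positive")


def _sigmoid(t: float) -> float:
    if t >= 0:
        return 1.0 / (1.0 + math.exp(-t))
    et = math.exp(t)
    return et / (1.0 + et)


def ads_desirability(x: float, p: ADSParams) -> float:
    """Raw (unnormalized) asymmetric double sigmoidal desirability D(x).

    D(x) = a + b·σ((x−c+d/2)/e)·[1 − σ((x−c−d/2)/f)], finite for all finite x.
    """
    rise = _sigmoid((x - p.c + p.d / 2.0) / p.e)
    fall = 1.0 - _sigmoid((x - p.c - p.d / 2.0) / p.f)
    return p.a + p.b * rise * fall


@dataclass(frozen=True)
class QEDParameterTable:
    """Per-descriptor ADS parameters and weights for the eight descriptors."""

    params: Mapping[str, ADSParams]
    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(DESCRIPTOR_NAMES) - set(self.params)
        if missing:
            raise ValueError(f"missing ADS parameters for {sorted(missing)}")
        if not any(w > 0 for w in self.weights.values()):
            raise ValueError("at least one weight must be positive")

    @classmethod
    def published(cls, weights: str = "mean") -> "QEDParameterTable":
        """The published QED parameterization; ``weights`` is ``"mean"``,
        ``"max"`` or ``"unit"`` (unit weights give the plain geometric mean)."""
        with resources.files("denovotki.data").joinpath("qed_params.json").open() as fh:
            raw = json.load(fh)
        params = {
            name: ADSParams(
                a=v["A"], b=v["B"], c=v["C"], d=v["D"], e=v["E"], f=v["F"],
                dmax=v["DMAX"],
            )
            for name, v in raw["ads"].items()
        }
        if weights == "unit":
            w = {name: 1.0 for name in DESCRIPTOR_NAMES}
        else:
            w = raw[f"weights_{weights}"]
        return cls(params=params, weights=w)


def qed(desc: DescriptorVector, table: QEDParameterTable | None = None) -> float:
    """Weighted geometric mean of normalized desirabilities, in (0, 1]."""
    if table is None:
        table = QEDParameterTable.published()
    num, den = 0.0, 0.0
    for name in DESCRIPTOR_NAMES:
        p = table.params[name]
        d = ads_desirability(getattr(desc, name), p) / p.dmax
        if d <= 0:
            raise ValueError(f"non-positive desirability for {name}")
        w = table.weights[name]
        num += w * math.log(d)
        den += w
    return math.exp(num / den)


def qed_for_smiles(smiles: str, table: QEDParameterTable | None = None) -> float:
    rec = parse_and_canonicalize(smiles)
    return qed(compute_descriptors(rec), table)


# --------------------------------------------------------------------------
# Synthetic accessibility
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SAComponents:
    fragment_score: float
    complexity_penalty: float
    sa_score: float


_SA_TABLE_CACHE: dict | None = None

# raw-score range the published scorer maps onto [1, 10]
_SA_RAW_MIN, _SA_RAW_MAX = -4.0, 2.5
_UNSEEN_FRAGMENT_SCORE = -4.0


def _default_sa_table_path() -> str | None:
    try:
        from rdkit import RDPaths

        path = os.path.join(RDPaths.RDContribDir, "SA_Score", "fpscores.pkl.gz")
        return path if os.path.exists(path) else None
    except Exception:
        return None


def load_fragment_contributions(path: str | None = None) -> dict[int, float]:
    """Load circular-fragment contribution values (fragment id -> score).

    Defaults to the frequency-derived table distributed with RDKit Contrib;
    raises if neither a path nor the default table is available.
    """
    global _SA_TABLE_CACHE
    if path is None and _SA_TABLE_CACHE is not None:
        return _SA_TABLE_CACHE
    path = path or _default_sa_table_path()
    if path is None:
        raise FileNotFoundError(
            "no fragment contribution table found; pass a path or build one "
            "with fragment_contributions_from_corpus()"
        )
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rb") as fh:
        raw = pickle.load(fh)
    table: dict[int, float] = {}
    for row in raw:
        for frag_id in row[1:]:
            table[frag_id] = float(row[0])
    _SA_TABLE_CACHE = table
    return table


def fragment_contributions_from_corpus(
    smiles_list: Iterable[str], radius: int = 2
) -> dict[int, float]:
    """Rebuild a contribution table as log10 relative frequencies of circular
    fragments over a user corpus (fallback when no published table exists)."""
    counts: Counter[int] = Counter()
    for s in smiles_list:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            continue
        fp = rdmd.GetMorganFingerprint(mol, radius)
        counts.update(fp.GetNonzeroElements())
    if not counts:
        raise ValueError("no valid molecules in corpus")
    total = sum(counts.values())
    # normalize so the most common fragment contributes ~+4, rare ones < 0
    top = counts.most_common(1)[0][1]
    return {
        frag: 4.0 + math.log10(c / top)
        for frag, c in counts.items()
        if 4.0 + math.log10(c / top) > -4.0
    }


def _num_bridgeheads_and_spiro(mol: Chem.Mol) -> tuple[int, int]:
    return (
        rdmd.CalcNumBridgeheadAtoms(mol),
        rdmd.CalcNumSpiroAtoms(mol),
    )


def sa_score(
    record: MoleculeRecord, fragment_table: Mapping[int, float] | None = None
) -> SAComponents:
    """Synthetic accessibility in [1, 10] (1 = trivial, 10 = very hard).

    Fragment score: contribution-weighted mean over the molecule's circular
    fragments (radius 2, with counts); fragments absent from the table get a
    fixed low contribution.  Complexity penalty: ring complexity (spiro +
    bridgehead), stereocenters, macrocycles, molecule size, and a symmetry
    correction that rewards repeated fragments.
    """
    if fragment_table is None:
        fragment_table = load_fragment_contributions()
    mol = record.mol()

    fp = rdmd.GetMorganFingerprint(mol, 2)
    frags = fp.GetNonzeroElements()
    score1 = 0.0
    nf = 0
    for frag_id, count in frags.items():
        nf += count
        score1 += fragment_table.get(frag_id, _UNSEEN_FRAGMENT_SCORE) * count
    score1 /= max(nf, 1)

    n_atoms = mol.GetNumAtoms()
    n_chiral = len(Chem.FindMolChiralCenters(mol, includeUnassigned=True))
    n_bridge, n_spiro = _num_bridgeheads_and_spiro(mol)
    n_macro = sum(1 for ring in mol.GetRingInfo().AtomRings() if len(ring) > 8)

    size_penalty = n_atoms**1.005 - n_atoms
    stereo_penalty = math.log10(n_chiral + 1)
    spiro_penalty = math.log10(n_spiro + 1)
    bridge_penalty = math.log10(n_bridge + 1)
    macro_penalty = math.log10(2) if n_macro > 0 else 0.0

    # symmetry correction: many atoms covered by few distinct fragments
    symmetry_bonus = 0.0
    if n_atoms > len(frags):
        symmetry_bonus = math.log(float(n_atoms) / len(frags)) * 0.5

    penalty = (
        size_penalty + stereo_penalty + spiro_penalty + bridge_penalty + macro_penalty
        - symmetry_bonus
    )
    raw = score1 - penalty

    # map raw range onto [1, 10] with soft compression of the hard tail
    scaled = 11.0 - (raw - _SA_RAW_MIN + 1.0) / (_SA_RAW_MAX - _SA_RAW_MIN) * 9.0
    if scaled > 8.0:
        scaled = 8.0 + math.log(scaled + 1.0 - 9.0)
    scaled = min(max(scaled, 1.0), 10.0)
    return SAComponents(fragment_score=score1, complexity_penalty=penalty, sa_score=scaled)


# --------------------------------------------------------------------------
# Parameter filter
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterCriteria:
    """Inclusive physicochemical screening window."""

    mw_range: tuple[float, float] = (300.0, 700.0)
    logp_range: tuple[float, float] = (2.0, 6.0)
    hbd_range: tuple[float, float] = (2.0, 6.0)
    hba_range: tuple[float, float] = (0.0, 12.0)
    hba_plus_hbd_max: float = 14.0
    tpsa_range: tuple[float, float] = (60.0, 140.0)
    rotb_max: float = 12.0

    def __post_init__(self) -> None:
        for f_ in fields(self):
            v = getattr(self, f_.name)
            if isinstance(v, tuple) and v[0] > v[1]:
                raise ValueError(f"{f_.name}: lower bound exceeds upper bound")

    def to_json(self) -> str:
        return json.dumps(
            {f_.name: getattr(self, f_.name) for f_ in fields(self)}
        )

    @classmethod
    def from_json(cls, text: str) -> "FilterCriteria":
        data = json.loads(text)
        data = {k: tuple(v) if isinstance(v, list) else v for k, v in data.items()}
        return cls(**data)


RULE_NAMES = ("MW", "LOGP", "HBD", "HBA", "HBA_HBD", "TPSA", "ROTB")


def parameter_filter(
    desc: DescriptorVector, criteria: FilterCriteria | None = None
) -> tuple[bool, list[str]]:
    """Apply every rule; returns (pass, names of violated rules)."""
    c = criteria or FilterCriteria()
    failed = []
    if not c.mw_range[0] <= desc.MW <= c.mw_range[1]:
        failed.append("MW")
    if not c.logp_range[0] <= desc.ALOGP <= c.logp_range[1]:
        failed.append("LOGP")
    if not c.hbd_range[0] <= desc.HBD <= c.hbd_range[1]:
        failed.append("HBD")
    if not c.hba_range[0] <= desc.HBA <= c.hba_range[1]:
        failed.append("HBA")
    if desc.HBA + desc.HBD > c.hba_plus_hbd_max:
        failed.append("HBA_HBD")
    if not c.tpsa_range[0] <= desc.PSA <= c.tpsa_range[1]:
        failed.append("TPSA")
    if desc.ROTB > c.rotb_max:
        failed.append("ROTB")
    return (not failed, failed)


@dataclass
class FilterReport:
    """Two-stage filter outcome: validity, deduplication, parameter window."""

    input_count: int
    valid_count: int
    unique_count: int
    passed: list[MoleculeRecord]
    rule_failures: dict[str, int] = field(default_factory=dict)

    @property
    def passed_count(self) -> int:
        return len(self.passed)


def filter_generated(
    smiles_list: Sequence[str], criteria: FilterCriteria | None = None
) -> FilterReport:
    """Validity filter, canonical-SMILES deduplication, then the parameter
    window; per-rule failure counts are over unique valid molecules."""
    criteria = criteria or FilterCriteria()
    valid: list[MoleculeRecord] = []
    for s in smiles_list:
        if not s:  # empty decodes count as invalid
            continue
        rec = parse_and_canonicalize(s)
        if rec.valid:
            valid.append(rec)
    seen: set[str] = set()
    unique: list[MoleculeRecord] = []
    for rec in valid:
        if rec.canonical_smiles not in seen:
            seen.add(rec.canonical_smiles)
            unique.append(rec)
    passed: list[MoleculeRecord] = []
    failures: dict[str, int] = defaultdict(int)
    for rec in unique:
        ok, failed = parameter_filter(compute_descriptors(rec), criteria)
        if ok:
            passed.append(rec)
        for rule in failed:
            failures[rule] += 1
    return FilterReport(
        input_count=len(smiles_list),
        valid_count=len(valid),
        unique_count=len(unique),
        passed=passed,
        rule_failures=dict(failures),
    )
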