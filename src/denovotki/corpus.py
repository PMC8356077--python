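"""Corpus curation, SMILES tokenization and enumeration augmentation.

The fine-tune corpus for the generative model is selected by drug-name
suffix (kinase inhibitors conventionally end in "-tinib"), optionally with
an explicit include list for compounds whose names break the convention.
Because the fine-tune set is small, it is expanded by SMILES enumeration:
each molecule is rewritten k times under a random atom ordering, which
changes the string but never the molecule.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chemio import MoleculeRecord

log = logging.getLogger(__name__)

START, END, PAD = "^", "$", " "
SPECIALS = (PAD, START, END)  # PAD first so its index is 0 everywhere

# multi-character lexemes first: bracket atoms, two-digit ring closures,
# two-letter organic-subset halogens
_TOKEN_RE = re.compile(r"(\[[^\]]+\]|%\d{2}|Cl|Br|.)")


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into chemically atomic tokens.

    ``detokenize(tokenize(s)) == s`` for every valid SMILES: bracket atoms
    like ``[nH]``, ring closures ``%nn`` and ``Cl``/``Br`` stay single tokens.
    """
    tokens = _TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        raise ValueError(f"untokenizable SMILES: {smiles!r}")
    return tokens


def detokenize(tokens: Sequence[str]) -> str:
    return "".join(tokens)


def select_by_name(
    records: Sequence[MoleculeRecord],
    suffix: str,
    include_names: Sequence[str] = (),
) -> list[MoleculeRecord]:
    """Select records whose name ends with ``suffix`` (case-insensitive) or
    matches ``include_names`` exactly; order-preserving, deduplicated by
    canonical SMILES keeping the first occurrence. Nameless records never
    match."""
    suffix = suffix.lower()
    include = {n.lower() for n in include_names}
    out: list[MoleculeRecord] = []
    seen: set[str] = set()
    for rec in records:
        if rec.name is None:
            continue
        name = rec.name.lower()
        if not (name.endswith(suffix) or name in include):
            continue
        key = rec.canonical_smiles if rec.valid else rec.raw_smiles
        if key in seen:
            continue
        seen.add(key)
        out.append(rec)
    return out


def augment(
    records: Sequence[MoleculeRecord], k: int, seed: int
) -> list[str]:
    """k-fold SMILES enumeration: k random atom-order rewrites per molecule.

    Sampling is with replacement (small molecules have few distinct
    enumerations), every output canonicalizes back to its source molecule,
    and the output is reproducible under a fixed seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    for rec in records:
        if not rec.valid:
            raise ValueError(f"cannot augment invalid record {rec.raw_smiles!r}")
        mol = rec.mol()
        n_atoms = mol.GetNumAtoms()
        for _ in range(k):
            perm = rng.permutation(n_atoms).tolist()
            shuffled = Chem.RenumberAtoms(mol, perm)
            out.append(Chem.MolToSmiles(shuffled, canonical=False))
    return out


@dataclass
class TokenizedCorpus:
    """Token-index sequences padded to a fixed length, plus their vocabulary.

    Every sequence is ``START tokens... END PAD...``; PAD has index 0.
    """

    vocabulary: list[str]
    sequences: list[list[int]]
    max_length: int
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {t: i for i, t in enumerate(self.vocabulary)}

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def pad_id(self) -> int:
        return self._index[PAD]

    @property
    def start_id(self) -> int:
        return self._index[START]

    @property
    def end_id(self) -> int:
        return self._index[END]

    def encode(self, smiles: str) -> list[int]:
        tokens = [START, *tokenize(smiles), END]
        if len(tokens) > self.max_length:
            raise ValueError(f"SMILES longer than max_length: {smiles!r}")
        try:
            ids = [self._index[t] for t in tokens]
        except KeyError as exc:
            raise ValueError(f"token {exc.args[0]!r} not in vocabulary") from None
        return ids + [self.pad_id] * (self.max_length - len(ids))

    def decode(self, ids: Sequence[int]) -> str:
        """Strip specials and reproduce the source SMILES."""
        tokens = []
        for i in ids:
            tok = self.vocabulary[i]
            if tok == END:
                break
            if tok in (START, PAD):
                continue
            tokens.append(tok)
        return detokenize(tokens)

    def to_array(self) -> np.ndarray:
        return np.asarray(self.sequences, dtype=np.int64)

    def save_vocabulary(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"vocabulary": self.vocabulary, "max_length": self.max_length}, fh)


def build_vocabulary(smiles_iterables: Sequence[Sequence[str]]) -> list[str]:
    """Union vocabulary over several corpora (so fine-tuning never meets an
    unseen token), deterministic order: specials, then sorted tokens."""
    tokens: set[str] = set()
    for smiles_list in smiles_iterables:
        for s in smiles_list:
            tokens.update(tokenize(s))
    return [*SPECIALS, *sorted(tokens)]


def build_corpus(
    smiles_list: Sequence[str],
    max_length: int = 120,
    vocabulary: Sequence[str] | None = None,
) -> TokenizedCorpus:
    """Tokenize and pad a SMILES list; strings that cannot fit within
    ``max_length`` after adding START/END are dropped with a logged count."""
    vocab = list(vocabulary) if vocabulary is not None else build_vocabulary([smiles_list])
    corpus = TokenizedCorpus(vocabulary=vocab, sequences=[], max_length=max_length)
    dropped = 0
    for s in smiles_list:
        if len(tokenize(s)) > max_length - 2:
            dropped += 1
            continue
        corpus.sequences.append(corpus.encode(s))
    if dropped:
        log.info("build_corpus: dropped %d string(s) over max_length", dropped)
    return corpus
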