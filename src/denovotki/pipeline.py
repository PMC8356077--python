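"""End-to-end orchestration: curate → augment → pretrain → fine-tune →
sample → filter → scaffold analysis → embed → affinity score → screen.

Every stage seed is derived deterministically from one global seed, so a
rerun with the same configuration reproduces the report bit for bit.  Stage
artifacts (.smi files, CSV score table, JSON report) are written when an
output directory is configured and are never overwritten without the
explicit flag.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit.Chem import DataStructs
from sklearn.manifold import TSNE

from . import corpus as corpus_mod
from . import dta as dta_mod
from . import generator as gen_mod
from . import scaffolds as scaf_mod
from . import scoring as scoring_mod
from . import synthetic_data as synth
from .chemio import (
    DESCRIPTOR_NAMES,
    Fingerprint,
    MoleculeRecord,
    compute_descriptors,
    morgan_fingerprint,
    parse_and_canonicalize,
    read_smi,
    write_smi,
)

log = logging.getLogger(__name__)


def embed_2d(fingerprints: Sequence[Fingerprint], perplexity: float,
             seed: int) -> np.ndarray:
    """Joint t-SNE embedding of fingerprints into 2D, one (x, y) per input;
    reproducible under a fixed seed. Raises when perplexity >= count."""
    n = len(fingerprints)
    if n < 3:
        raise ValueError("need at least 3 fingerprints")
    if perplexity >= n:
        raise ValueError("perplexity must be smaller than the number of points")
    X = np.zeros((n, fingerprints[0].nbits), dtype=np.float32)
    for i, fp in enumerate(fingerprints):
        arr = np.zeros(fp.nbits, dtype=np.int8)
        DataStructs.ConvertToNumpyArray(fp.bits, arr)
        X[i] = arr
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                init="pca", n_jobs=1)
    return tsne.fit_transform(X)


def novelty_stats(generated: Sequence[str], train: Sequence[str],
                  radius: int = 2, nbits: int = 2048) -> dict:
    """Per-generated-molecule nearest-neighbour Tanimoto to the training set.

    Returns the full distribution plus its mean and the fraction of exact
    training-set copies (similarity == 1 at the fingerprint level).
    """
    if not generated or not train:
        raise ValueError("both sets must be non-empty")
    train_fps = [
        morgan_fingerprint(parse_and_canonicalize(s), radius, nbits).bits
        for s in train
    ]
    values = []
    for s in generated:
        fp = morgan_fingerprint(parse_and_canonicalize(s), radius, nbits).bits
        sims = DataStructs.BulkTanimotoSimilarity(fp, train_fps)
        values.append(max(sims))
    values = np.asarray(values)
    return {
        "nearest_neighbor_tanimoto": values,
        "mean": float(values.mean()),
        "copy_fraction": float(np.mean(values == 1.0)),
    }


@dataclass
class PipelineConfig:
    """Desk-scale defaults; the historical campaign sizes (sample 10,316,
    top 360) remain the documented full-scale settings."""

    n_base: int = 2000
    n_finetune: int = 139
    augmentation_k: int = 10
    sample_n: int = 1000
    top_k: int = 360
    n_affinity_pairs: int = 2000
    n_proteins: int = 6
    max_length: int = 120
    name_suffix: str = "tinib"
    include_names: tuple[str, ...] = ()
    generator: gen_mod.GeneratorConfig = field(
        default_factory=lambda: gen_mod.GeneratorConfig(hidden_units=64, embedding_dim=32)
    )
    finetune_epochs: int = 30
    dta: dta_mod.DTAModelConfig = field(
        default_factory=lambda: dta_mod.DTAModelConfig(protein_max_len=500, epochs=20)
    )
    criteria: scoring_mod.FilterCriteria = field(default_factory=scoring_mod.FilterCriteria)
    perplexity: float = 30.0
    seed: int = 0
    base_smi: str | None = None       # optional real inputs replacing synthesis
    finetune_smi: str | None = None
    protein_fasta: str | None = None
    affinity_csv: str | None = None
    output_dir: str | None = None
    overwrite: bool = False


@dataclass
class PipelineReport:
    counts: dict
    descriptor_summary: dict
    novelty: dict
    csk_layers: dict
    csk_containment: dict
    screened: list
    dta_final_loss: float | None
    embedding: list
    seed: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def _stage_seeds(seed: int, n: int = 10) -> list[int]:
    return [int(s.generate_state(1)[0] % 2**31)
            for s in np.random.SeedSequence(seed).spawn(n)]


def _summary(records: Sequence[MoleculeRecord]) -> dict:
    rows = {k: [] for k in DESCRIPTOR_NAMES}
    for rec in records:
        d = compute_descriptors(rec)
        for k in DESCRIPTOR_NAMES:
            rows[k].append(getattr(d, k))
    return {
        k: {"mean": float(np.mean(v)), "min": float(np.min(v)), "max": float(np.max(v))}
        for k, v in rows.items() if v
    }


def _read_protein_fasta(path: str) -> str:
    from Bio import SeqIO

    return str(next(SeqIO.parse(path, "fasta")).seq)


def _read_affinity_csv(path: str) -> list[dta_mod.AffinityRecord]:
    import pandas as pd

    df = pd.read_csv(path)
    return [
        dta_mod.AffinityRecord(ligand_smiles=r.smiles, protein_sequence=r.protein,
                               kd=float(r.kd_nM))
        for r in df.itertuples()
    ]


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute all stages in order and return (and optionally write) the
    report. Counts along generated → valid → unique → filtered → screened
    are monotone non-increasing by construction."""
    t0 = time.time()
    seeds = _stage_seeds(config.seed)
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir is not None:
        if outdir.exists() and any(outdir.iterdir()) and not config.overwrite:
            raise FileExistsError(f"{outdir} is not empty; pass overwrite=True")
        outdir.mkdir(parents=True, exist_ok=True)

    # -- inputs ------------------------------------------------------------
    if config.base_smi:
        base = [r for r in read_smi(config.base_smi) if r.valid]
    else:
        base = synth.gen_base_corpus(synth.SyntheticSpec(n=config.n_base, seed=seeds[0]))
    if config.finetune_smi:
        finetune_raw = read_smi(config.finetune_smi)
    else:
        finetune_raw = synth.gen_finetune_corpus(
            synth.SyntheticSpec(n=config.n_finetune, seed=seeds[1]))
    log.info("inputs: %d base, %d fine-tune candidates", len(base), len(finetune_raw))

    # -- curation + augmentation -------------------------------------------
    tinib = corpus_mod.select_by_name(finetune_raw, config.name_suffix,
                                      config.include_names)
    augmented = corpus_mod.augment(tinib, config.augmentation_k, seeds[2])
    base_smiles = [r.canonical_smiles for r in base]
    vocab = corpus_mod.build_vocabulary([base_smiles, augmented])
    base_corpus = corpus_mod.build_corpus(base_smiles, config.max_length, vocab)
    ft_corpus = corpus_mod.build_corpus(augmented, config.max_length, vocab)

    # -- generative model ---------------------------------------------------
    from dataclasses import replace

    gcfg = replace(config.generator, seed=seeds[3])
    model = gen_mod.pretrain(base_corpus, gcfg)
    model = gen_mod.fine_tune(
        model, ft_corpus, replace(gcfg, epochs=config.finetune_epochs, seed=seeds[4]))
    log.info("generator trained (final loss %.3f)", model.training_log[-1])

    # -- sampling + filtering ----------------------------------------------
    sampled = gen_mod.sample(model, config.sample_n, seed=seeds[5]) if config.sample_n else []
    report_f = scoring_mod.filter_generated(sampled, config.criteria)
    passed = report_f.passed
    log.info("sampled %d, valid %d, unique %d, passed %d",
             len(sampled), report_f.valid_count, report_f.unique_count, len(passed))

    # -- scaffold analysis --------------------------------------------------
    scaffold_records = [scaf_mod.scaffold_record(r) for r in passed]
    hierarchy = scaf_mod.csk_hierarchy(scaffold_records)
    layer_counts = (
        hierarchy.groupby("layer")["count"].sum().to_dict() if len(hierarchy) else {}
    )
    containment = scaf_mod.containment_counts(scaffold_records)

    # -- novelty + embedding ------------------------------------------------
    train_smiles = [r.canonical_smiles for r in tinib]
    novelty: dict = {}
    embedding: list = []
    if passed and train_smiles:
        novelty = novelty_stats([r.canonical_smiles for r in passed], train_smiles)
        novelty = {"mean": novelty["mean"], "copy_fraction": novelty["copy_fraction"]}
        all_fps = [morgan_fingerprint(r) for r in (*tinib, *passed)]
        if len(all_fps) >= 5:
            perp = min(config.perplexity, (len(all_fps) - 1) / 3.0)
            coords = embed_2d(all_fps, perp, seeds[6])
            labels = ["train"] * len(tinib) + ["generated"] * len(passed)
            embedding = [
                [lab, float(x), float(y)] for lab, (x, y) in zip(labels, coords)
            ]

    # -- affinity model -----------------------------------------------------
    if config.affinity_csv:
        pairs = _read_affinity_csv(config.affinity_csv)
    else:
        proteins = synth.gen_proteins(config.n_proteins, seeds[7])
        pairs = synth.gen_affinity_pairs(
            synth.SyntheticSpec(n=config.n_affinity_pairs, seed=seeds[8]),
            base + tinib, proteins).records
    target = (_read_protein_fasta(config.protein_fasta) if config.protein_fasta
              else pairs[0].protein_sequence)

    screened: list[tuple[str, float]] = []
    final_loss = None
    if passed:
        dcfg = config.dta
        dcfg.seed = seeds[9]
        dcfg.smiles_vocab = dta_mod.build_vocab(
            [p.ligand_smiles for p in pairs] + [r.canonical_smiles for r in passed])
        dta_model = dta_mod.train_dta(pairs, dcfg)
        final_loss = dta_model.training_log[-1]
        train_set = set(train_smiles) | set(base_smiles)
        candidates = [r.canonical_smiles for r in passed
                      if r.canonical_smiles not in train_set]
        scores = dta_mod.predict_affinity(dta_model, candidates, target)
        screened = dta_mod.rank_and_screen(list(zip(candidates, scores)),
                                           top_k=config.top_k)

    report = PipelineReport(
        counts={
            "base": len(base),
            "finetune_curated": len(tinib),
            "augmented": len(augmented),
            "generated": len(sampled),
            "valid": report_f.valid_count,
            "unique": report_f.unique_count,
            "filtered_pass": len(passed),
            "screened": len(screened),
            "rule_failures": report_f.rule_failures,
        },
        descriptor_summary={
            "train": _summary(tinib),
            "generated": _summary(passed),
        },
        novelty=novelty,
        csk_layers={str(k): int(v) for k, v in layer_counts.items()},
        csk_containment=containment,
        screened=[[s, float(p)] for s, p in screened],
        dta_final_loss=final_loss,
        embedding=embedding,
        seed=config.seed,
    )

    if outdir is not None:
        write_smi([parse_and_canonicalize(s) for s in sampled if s],
                  outdir / "generated.smi")
        write_smi(passed, outdir / "filtered.smi")
        hierarchy.to_csv(outdir / "csk_hierarchy.csv", index=False)
        with open(outdir / "screened.csv", "w") as fh:
            fh.write("rank,smiles,pkd\n")
            for i, (s, p) in enumerate(screened, 1):
                fh.write(f"{i},{s},{p}\n")
        (outdir / "report.json").write_text(report.to_json())
    log.info("pipeline finished in %.1f s", time.time() - t0)
    return report
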