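"""Shared fixtures.

The expensive study fixtures (trained generator, trained affinity model)
are session-scoped and shared between the module tests and the acceptance
tests so each training run happens once per session.
"""

from dataclasses import replace

import numpy as np
import pytest

from denovotki import (
    DTAModelConfig,
    GeneratorConfig,
    SyntheticSpec,
    augment,
    build_corpus,
    build_vocabulary,
    fine_tune,
    gen_base_corpus,
    gen_finetune_corpus,
    pretrain,
    sample,
    train_dta,
)
from denovotki.synthetic_data import gen_affinity_pairs, gen_proteins


@pytest.fixture(scope="session")
def base_corpus_small():
    """60 diverse assembled molecules (includes the filter edge panel)."""
    return gen_base_corpus(SyntheticSpec(n=60, seed=11))


@pytest.fixture(scope="session")
def finetune_corpus_small():
    """25 named inhibitor-like molecules sharing the fused bicyclic core."""
    return gen_finetune_corpus(SyntheticSpec(n=25, seed=12))


@pytest.fixture(scope="session")
def generator_study():
    """The generator study conditions: pretrain on 500 diverse molecules,
    fine-tune on a coherent 50-molecule family (10-fold augmented), and a
    memorization run on a 10-string corpus. Fixed seeds throughout."""
    base = gen_base_corpus(SyntheticSpec(n=500, seed=101))
    family = gen_finetune_corpus(SyntheticSpec(n=50, seed=102))
    base_smiles = [r.canonical_smiles for r in base]
    augmented = augment(family, 10, seed=103)
    vocab = build_vocabulary([base_smiles, augmented])
    corpus = build_corpus(base_smiles, 110, vocab)
    ft_corpus = build_corpus(augmented, 110, vocab)
    config = GeneratorConfig(hidden_units=96, embedding_dim=32, epochs=30,
                             batch_size=64, seed=104)
    model = pretrain(corpus, config)
    tuned = fine_tune(model, ft_corpus, replace(config, epochs=20, seed=105))
    ten = [r.canonical_smiles for r in family[:10]]
    ten_corpus = build_corpus(ten, 110, vocab)
    memorizer = fine_tune(model, ten_corpus, replace(config, epochs=300, seed=106))
    return {
        "base": base,
        "family": family,
        "vocab": vocab,
        "corpus": corpus,
        "ft_corpus": ft_corpus,
        "config": config,
        "pretrained": model,
        "finetuned": tuned,
        "memorizer": memorizer,
        "ten_strings": ten,
        "samples_pre": sample(model, 200, seed=107),
        "samples_post": sample(tuned, 200, seed=107),
    }


@pytest.fixture(scope="session")
def dta_study():
    """2,000 synthetic affinity pairs (noise sd 0.3), 1,600/400 split, and a
    trained CNN regressor with its held-out predictions."""
    base = gen_base_corpus(SyntheticSpec(n=300, seed=201))
    family = gen_finetune_corpus(SyntheticSpec(n=100, seed=202))
    proteins = gen_proteins(6, 203)
    data = gen_affinity_pairs(SyntheticSpec(n=2000, seed=204), base + family, proteins)
    train, test = data.records[:1600], data.records[1600:]
    config = DTAModelConfig(protein_max_len=500, smiles_max_len=100,
                            epochs=15, seed=205)
    model = train_dta(train, config)
    from denovotki.dta import encode_pairs

    Xs, Xp = encode_pairs(test, config)
    pred, _ = model.forward(Xs, Xp, train=False)
    return {
        "dataset": data,
        "train": train,
        "test": test,
        "truth_test": data.truth[1600:],
        "config": config,
        "model": model,
        "pred_test": np.asarray(pred),
    }
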