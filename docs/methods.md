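# Methods

`denovotki` implements a complete de novo design loop for
kinase-inhibitor-like small molecules: corpus curation → SMILES language
model with transfer learning → physicochemical and drug-likeness filtering
→ cyclic-skeleton analysis → CNN affinity ranking. This note documents the
models, the parameters that matter, the synthetic data the tests run on,
and the design decisions taken where the design was genuinely open.

## Generative model

The generator is a character-level language model over SMILES: tokens are
single characters except two-letter halogens (`Cl`, `Br`), bracket atoms
(`[nH]`), and two-digit ring closures (`%nn`), plus START/END/PAD specials.
The network is a stack of LSTM layers trained to predict the next token;
the loss is token-level cross-entropy averaged over non-PAD positions (PAD
targets are masked out, so appending padding never changes the loss).

Canonical hyperparameters, kept as defaults in `GeneratorConfig`:

| parameter | default | meaning |
|---|---|---|
| `num_lstm_layers` | 2 | stacked LSTM layers |
| `hidden_units` | 512 | units per layer |
| `keep_probability` | 0.8 | dropout keep probability, applied to each layer's output at train time only (recurrent connections undropped) |
| `learning_rate` | 0.003 | Adam step size |
| `temperature` | 0.75 | sampling softmax temperature; below 1e-4 decoding is greedy |

Transfer learning is plain warm-started continuation: fine-tuning clones
the pretrained weights and continues optimization on the small target
corpus (10-fold enumeration-augmented), leaving the input model untouched.
Augmentation rewrites each molecule k times under a random atom ordering
(seed-controlled atom renumbering followed by non-canonical SMILES
writing), which changes the string but never the molecule; duplicates are
permitted when the enumeration space is small. The token vocabulary is
built from the union of base and fine-tune corpora before pretraining so
fine-tuning never meets an unseen token.

The networks are implemented directly in NumPy (manual backpropagation,
Adam, global-norm gradient clipping at 5); gradient correctness is checked
against finite differences in the test suite. Everything runs in float32
on a single CPU. Tests and the reproduction script use smaller instances
(hidden 24–96 units, embedding 12–32, corpora of 120–2,000 molecules)
— the package's desk-scale study conditions; the full-scale defaults above
remain available through the config.

## Drug-likeness scoring

Each of the eight QED descriptors (MW, ALOGP, HBA, HBD, PSA, ROTB, AROM,
ALERTS) is mapped to a desirability by an asymmetric double sigmoidal
curve

    D(x) = a + b·σ((x − c + d/2)/e)·[1 − σ((x − c − d/2)/f)]

evaluated in a numerically stable sigmoid form (finite for all finite x),
normalized by the curve's maximum, and combined as a weighted geometric
mean `QED = exp(Σ wᵢ ln dᵢ / Σ wᵢ)` — scale-invariant in the weights, in
(0, 1]. The published parameterization (ADS coefficients, normalization
maxima, mean/max weight sets, acceptor and structural-alert SMARTS) ships
as a versioned JSON data file; unit weights are available as an option.
Descriptor definitions mirror the reference implementation (acceptors =
total matches of the acceptor SMARTS set; ALERTS = number of alert
patterns with at least one match; aromatic rings counted by SSSR after
deleting aliphatic rings), and the test suite checks agreement with the
independent reference to 1e-3.

Synthetic accessibility is fragment score minus complexity penalty, scaled
to [1, 10] (lower = easier to synthesize). The fragment score is the
contribution-weighted mean over the molecule's radius-2 circular fragments
with counts; fragments absent from the table contribute −4. The complexity
penalty sums a size term (n^1.005 − n over heavy atoms), log-penalties for
stereocenters, spiro and bridgehead atoms, a macrocycle term (ring size
> 8), minus a symmetry correction rewarding repeated fragments. The
fragment contribution table is a frequency analysis over a large compound
collection; it is loaded at run time from the chemistry toolkit's Contrib
distribution, and `fragment_contributions_from_corpus` can rebuild a
log-frequency table from any user corpus when no table is available.
Agreement with the reference scorer is checked to 0.05.

## Physicochemical filter

The hard screening window (all bounds inclusive, all configurable):
300 ≤ MW ≤ 700, 2.0 ≤ LogP ≤ 6.0, 2.0 ≤ HBD ≤ 6.0, 0 ≤ HBA ≤ 12,
HBA + HBD ≤ 14, 60 ≤ TPSA ≤ 140, rotatable bonds ≤ 12. The HBD lower
bound of 2 is implemented exactly as specified even though it excludes
low-donor molecules (many marketed kinase inhibitors have one donor); a
custom `FilterCriteria` relaxes it. One structural consequence worth
knowing: an HBA-only violation is impossible under this window — failing
HBA needs ≥ 13 acceptors while HBD must stay within [2, 6], which forces
HBA + HBD ≥ 15 and always trips the sum rule. The synthetic edge panel
therefore carries the minimal violation set {HBA, HBA+HBD} for that rule.

Generated sets are filtered in two stages: validity (parse + sanitize;
empty decodes count as invalid), deduplication by canonical SMILES, then
the parameter window, with per-rule failure counts reported.

## Scaffolds and cyclic skeletons

The Murcko scaffold keeps ring systems plus connecting linkers; the cyclic
skeleton (CSK) additionally sets every heavy atom to carbon and every bond
to single (charges, stereochemistry and aromaticity cleared), so pyridine
and benzene collapse to one skeleton; the operation is idempotent.
Skeletons are layered by SSSR ring count and two-ring skeletons are
classified by ring-atom sharing: 0 shared atoms → linked, 1 → spiro,
2 → fused, > 2 → bridged. Skeletons with three or more rings are reported
by ring count and additionally through a containment view (the set of
pair classes over all SSSR ring pairs), since a tricyclic molecule can
simultaneously contain a fused and a bridged pair.

## Affinity model

Affinity is pKd = −log10(Kd/1e9) with Kd in nM (1 nM → 9.0). The
regressor is a two-branch sequence CNN: ligand SMILES and protein sequence
are label-encoded at character level (0 reserved for padding; defaults 100
ligand / 1,000 protein positions), embedded, passed through three stacked
1-D convolutions per branch with ReLU and a global max pool, concatenated,
and mapped through two ReLU dense layers with dropout to a scalar pKd,
trained by MSE. Screening ranks candidates by predicted pKd (ties broken
lexicographically) and keeps the top k; the "stringent criterion" of the
original campaign workflow is operationally undefined there, so it is
re-defined here as: valid ∧ passed the parameter filter ∧ not an exact
training-set molecule ∧ affinity rank within top k — a deliberate
reinterpretation, flagged as such.

## Synthetic data

The generators replace the external compound database so every stage runs
without a download. Molecules are built by fragment assembly — random
substituents bonded at hydrogen-bearing atoms of a sampled scaffold — so
validity is guaranteed and property placement is controllable.

* **Base corpus**: 12 diverse scaffolds (benzene, cyclohexane, pyridine,
  pyrimidine, piperidine, piperazine, morpholine, naphthalene, quinoline,
  indole, thiophene, tetrahydropyran) with 0–4 substituents from a
  28-fragment pool. The first seven slots hold a frozen *edge panel* of
  designed molecules whose filter-violation sets are known exactly, so the
  corpus provably exercises every rule.
* **Fine-tune corpus**: every molecule shares a fused 6-6 N-heterocyclic
  (quinazoline) core with 3–5 inhibitor-flavoured decorations (anilines,
  acrylamide, sulfonamide, urea, ethers) sized so the family's descriptor
  distributions centre inside the screening window, and carries a
  pronounceable synthesized name ending in "tinib"; within-family mean
  pairwise Tanimoto exceeds the base corpus's.
* **Proteins**: random 200–500-mers over the 20-letter alphabet, each with
  a random subset of three motifs (HKWWH, CDEYC, KDDKG) planted at random
  positions.
* **Affinity pairs**: pKd = α + β·s(ligand, protein) + N(0, σ), defaults
  α = 5, β = 1, σ = 0.3, Kd back-computed exactly. The ground-truth score
  s is fully documented and presence-based: functional-group substrings of
  the canonical SMILES (sulfonyl +0.8, trifluoromethyl +0.6, fused diazine
  +0.7, dimethylamino +0.4, chloro −0.5), protein motifs (+1.0, +0.6,
  −0.4), and one interaction term (+0.5 when the fused diazine meets the
  HKWWH motif). Presence features are exactly the kind of signal a
  convolution-plus-max-pool architecture can detect, so recovery tests
  measure the model, not an impossible task.

What the synthetic data does *not* emulate: real structure–activity
landscapes, activity cliffs, assay noise structure, tautomers and
stereochemistry, or the property distributions of a curated database
beyond straddling the filter bounds. Passing tests therefore demonstrate
that the machinery is correct and trainable, not that it would rediscover
clinical-grade chemistry.

## Numerical choices and degenerate inputs

Invalid SMILES are a data state, never an exception; empty sampled strings
count as invalid. Canonical SMILES define identity everywhere
(deduplication, train-copy exclusion, augmentation checks). Stage seeds
are spawned deterministically from one global seed; identical
configurations reproduce reports bit for bit. The t-SNE embedding uses
PCA initialization and a fixed random state, and the pipeline clips the
perplexity below the point count rather than erroring mid-run. Ranking
ties break lexicographically so screening is a deterministic permutation.
Zero-sample runs produce well-formed empty reports.

## Known limitations

* Hand-written NumPy networks are CPU-bound; the full historical scale
  (~2M-molecule pretraining corpus, 10,316-sample generation) is out of
  reach at desk scale, and no GPU path exists.
* Absolute pKd predictions are only as meaningful as the affinity training
  table; with synthetic pairs they live on the synthetic scale.
* No docking, covalent-binding determination, or kinase selectivity
  analysis; screening stops at predicted-affinity ranking.
* Stereochemistry is untouched by design (no enumeration, no 3D).
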