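"""Physicochemical filtering, QED and synthetic accessibility.

Scores a few reference molecules, then pushes a synthetic corpus through
the two-stage filter (validity, then the inclusive screening window
300<=MW<=700, 2<=LogP<=6, 2<=HBD<=6, HBA<=12, HBA+HBD<=14, 60<=TPSA<=140,
rotatable bonds<=12) and reports what failed where.
"""

from denovotki import (
    SyntheticSpec, compute_descriptors, filter_generated, gen_base_corpus,
    parse_and_canonicalize, qed_for_smiles, sa_score,
)

for name, smi in [("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
                  ("a quinazoline core", "c1ccc2ncncc2c1"),
                  ("ethanol", "CCO")]:
    rec = parse_and_canonicalize(smi)
    d = compute_descriptors(rec)
    print(f"{name}: MW={d.MW:.1f} LogP={d.ALOGP:.2f} TPSA={d.PSA:.1f} "
          f"QED={qed_for_smiles(smi):.3f} SA={sa_score(rec).sa_score:.2f}")

corpus = gen_base_corpus(SyntheticSpec(n=200, seed=4))
report = filter_generated([r.canonical_smiles for r in corpus])
print(f"\n{report.input_count} molecules -> {report.valid_count} valid, "
      f"{report.unique_count} unique, {report.passed_count} pass the window")
print("failures per rule:", dict(sorted(report.rule_failures.items())))
# QED near 1 means drug-like; SA near 1 means easy to synthesize; the rule
# counts show which bound each rejected molecule violated
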