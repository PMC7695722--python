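"""Simulate a cognate dataset and binarize it.

Builds a synthetic language family on a dated tree with extinct tips,
emits a multistate cognate table (with loanwords, synonyms and missing
entries), removes the loans, and converts the result to the binary
presence/absence matrix used by the likelihood.
"""

import phylolex as px

cfg = px.SimulationConfig(seed=11, n_concepts=40, root_age=5.0,
                          fbd=px.FBDParams(birth=0.9, death=0.25, psi=0.1,
                                           rho=0.85),
                          loan_rate=0.03, synonym_rate=0.03,
                          missing_rate=0.05)
ds, truth = px.make_cognate_dataset(cfg)

print(f"simulated {len(ds.languages)} languages x {len(ds.concepts)} "
      f"concepts on a tree with root age "
      f"{truth.tree.root_age:.2f} ka")
extinct = [t.label for t in truth.tree.tips() if t.age > 0]
print(f"extinct languages (tip dates fixed by their last-seen ages): "
      f"{extinct}")
print(f"{ds.n_loans} loan-flagged entries")

clean = px.remove_loans(ds)
bm = px.multistate_to_binary(clean)
pats = px.compress_patterns(bm)
print(f"binary matrix: {bm.n_cognate_sets} cognate sets "
      f"({pats.n_patterns} unique site patterns after compression)")
# Each cognate set is one 0/1/? column: 1 = the language attests that
# cognate class, 0 = it attests the concept through another class,
# ? = the concept is missing for that language.
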