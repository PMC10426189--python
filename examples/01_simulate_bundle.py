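"""Generate a synthetic two-ontology bundle and inspect its ground truth.

The bundle contains a phenotype-like ontology (HPX, five branch roots, one
dominant branch), a function-like ontology (GOX), gene and disease
annotations, planted cross-ontology equivalences (emitted both as logical
definitions and as confidence-scored mappings), and gene-disease labels
driven by the annotation overlap scores.
"""

from ontogda import FixtureSpec, fixture_truth_table, make_fixture_bundle

spec = FixtureSpec(seed=7)
bundle = make_fixture_bundle(spec)

print(f"phenotype ontology: {len(bundle.hp_ontology.classes)} classes, "
      f"{len(bundle.hp_ontology.roots)} branch roots")
print(f"function ontology:  {len(bundle.go_ontology.classes)} classes")
print(f"cross-ontology links: {len(bundle.cross_links)} "
      f"(all under branch {bundle.signal_branch_root})")
print(f"positive associations: {len(bundle.positives)}")

truth = fixture_truth_table(bundle)
pos = truth.query("label == 1")
print(f"positives with cross-link support: {(pos['cross'] > 0).mean():.0%}")
# The 'direct' column counts shared phenotype annotations, 'cross' counts
# disease phenotype classes whose equivalence partner is annotated to the
# gene; the label thresholds their weighted sum per disease.
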