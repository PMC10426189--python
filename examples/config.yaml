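# Example pipeline configuration for `ontogda run-all`.
# Exactly one of `fixture:` (synthetic bundle) or `inputs:` (files on disk)
# must be present.
seed: 7
variant: HPs+GO+LD
mapping_threshold: 0.8
fixture:
  n_classes: 60
  n_classes_go: 40
  n_genes: 30
  n_diseases: 15
  gene_go_annotations: 6
  disease_hp_annotations: 6
  n_cross_links: 12
  positive_rate: 0.1
embedding:
  method: rdf2vec   # rdf2vec | axiom-sentence | transe | distmult
  dim: 200
  walks: 50
  depth: 2
  window: 2
  epochs: 5
dataset:
  k: 10
  banned_sources: [UNIPROT, OMIM, ORPHANET]
predict:
  predictor: cosine  # rf | xgb | cosine
  operator: hadamard
# For real inputs replace `fixture:` with:
# inputs:
#   hp_obo: data/hp.obo
#   go_obo: data/go.obo
#   gene_hp: data/gene_hp_annotations.tsv
#   gene_go: data/gene_go_annotations.gaf
#   disease_hp: data/phenotype.hpoa
#   lds: data/hp_logical_definitions.owl
#   mappings: data/aml_compound_mappings.tsv
#   associations: data/disgenet_curated.tsv
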