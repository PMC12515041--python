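table: study/table.tsv
metadata: study/metadata.tsv
taxonomy: study/taxonomy.tsv
phenotypes: study/phenotypes.tsv
out_dir: run
depth: 4000
alpha: 0.05
n_perm: 199
protest_perm: 99
seed: 3
boruta_iter: 60
boruta_trees: 150
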