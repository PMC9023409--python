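# GR-like desk-scale experiment: rehabilitation-style cohort (n=450,
# baseline + post-treatment), MAR dropout weighted toward poor self-rated
# health, three missingness levels.  Full-scale runs use n_replicates: 100
# and m_imputations: 100 over all eight levels.
cohort_preset: gr
value_set: synthetic-5l
levels: [10, 35, 65]
mechanism: mar
n_replicates: 20
m_imputations: 10
approaches: [cc, available, mi_score, mi_item]
seed: 0
out_dir: results/gr_like
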