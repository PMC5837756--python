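# Synthetic paired-cohort experiment: five young-specific planted regions
# plus one region present in both age groups (subtracted by specificity).
simulate = true
seed = 1
n_young = 120
n_old = 300
noise_rate = 0.2

# thresholds (defaults shown explicitly)
min_probes = 10
min_seg_size = 1000
min_clique = 2
min_patients = 5
min_mcr_size = 1000
young_cutoff = 45
specificity_policy = any-overlap

# chrom:start:end:type:group:penetrance:jitter[:beta[:gamma]]
planted_region = 1:50000000:50250000:gain:young:0.45:300:1.0:0.7
planted_region = 2:100000000:100300000:loss:young:0.4:300:0.8
planted_region = 5:60000000:60200000:gain:young:0.35:300
planted_region = 8:20000000:20250000:loss:young:0.5:300
planted_region = 11:30000000:30300000:gain:young:0.4:300
planted_region = 17:40000000:40200000:gain:both:0.4:300
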