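# Demo pipeline configuration: simulate one Cameroon-like cohort at the
# survey's design scale and run the full analysis into ./demo_run/.
country: cameroon
seed: 1
out_dir: demo_run
n_clusters: 51
cluster_size: 80
threshold: alot      # primary self-report case definition
min_domains: 1
depression_case_band: moderately_severe
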