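# Demo configuration: a small synthetic study with planted effects.
# Analysis thresholds follow the published procedure: three-read coverage
# filter, 1.2-fold site threshold, Kruskal-Wallis bin test with BH
# correction at alpha = 0.05, DE thresholds q <= 0.05 and |log2FC| >= 0.60,
# duplex search up to score 4.5.
seed = 7
min_coverage = 3
fc_threshold = 1.2
bin_size = 100
min_sites = 5
alpha = 0.05
de_alpha = 0.05
de_lfc = 0.60
max_score = 4.5

[simulation]
chromosome_length = 20000
n_genes = 8
coverage_mean = 30.0

[[simulation.dmr_plan]]
chrom = "A01"
start = 5001
end = 5450
context = "CG"
delta = 0.30

[[simulation.dmr_plan]]
chrom = "C01"
start = 8001
end = 8400
context = "CHG"
delta = -0.15
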