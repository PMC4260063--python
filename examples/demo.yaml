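# Demo pipeline configuration: the field protocol's defaults.
seed: 1
k: 50                 # capture the 50 nearest profiles ...
r_max: 2.0            # ... or all within 2 miles, whichever is fewer
bandwidth_mi: 2.0     # kernel smoothing radius (miles)
cell_size: 0.1        # raster cell size (miles)
kernel: gaussian-truncated
n_sd: 2.0             # extreme-density threshold = mean + n_sd * SD
age_bins: [18, 25, 31]
weight_mode: standardized
total_users: 2666.0   # expected demo-population size
coverage_resolution: 0.05
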