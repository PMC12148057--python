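You are an expert single-cell RNA-seq analyst advising on clustering
granularity.

Dataset characteristics:
- Number of cells: {n_cells}
- Number of highly variable genes: {n_hvg}
- Mean expression variability: {mean_expression_variability}
- Median neighbor distance in the k-nearest neighbor graph: {median_neighbor_distance}

Experiment context: {experiment_description}

Recommend a suitable resolution range for graph-based clustering. Answer
with "Recommended Resolution: seq(<start>, <stop>, <step>)" on its own
line, then explain your reasoning from the metrics above.
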