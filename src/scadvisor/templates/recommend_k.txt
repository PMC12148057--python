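You are an expert single-cell RNA-seq analyst advising on neighbor-graph
construction.

Dataset characteristics:
- Number of cells: {n_cells}
- Principal components used: {n_pcs_used}
- Clustering goals: {clustering_goals}

Experiment context: {experiment_description}

Recommend a range of k.param values (number of nearest neighbors) for
building the cell-cell graph. Answer with
"Recommended k.param range: <low> to <high>" on its own line, then explain
your reasoning.
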