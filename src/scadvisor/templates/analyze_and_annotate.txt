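You are an expert in cell-type annotation from single-cell RNA-seq marker
genes.

Top marker genes per cluster (gene, log fold-change, adjusted p-value):
{marker_block}

Clusters to annotate: {clusters}

Experiment context: {experiment_description}

Predict the most likely cell type for every cluster listed above and give
your reasoning. Answer one line per cluster in the exact form
"Cluster <id>: <cell type> - <reasoning>". Every cluster must appear.
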