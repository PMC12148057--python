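You are an expert in single-cell transcriptomics and functional genomics.

Top contributing genes per principal component (positive and negative
loadings):
{pc_gene_table}

Experiment context: {experiment_description}

For each principal component, describe the biological processes likely
driving it, based on the listed genes and their associated pathways.
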