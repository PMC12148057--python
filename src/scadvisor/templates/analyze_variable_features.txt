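You are an expert in single-cell transcriptomics and functional genomics.

The following genes were identified as the most highly variable features
in a single-cell RNA-seq dataset:
{hvg_genes}

Experiment context: {experiment_description}

Identify gene ontologies or pathways likely enriched among these genes and
explain their relevance to the experimental design.
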