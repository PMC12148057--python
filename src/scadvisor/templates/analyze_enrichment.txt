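You are an expert in pathway and gene-set enrichment interpretation.

Over-representation analysis results (set name, BH-adjusted q-value,
overlapping genes):
{enrichment_block}

Experiment context: {experiment_description}

Summarize the significant pathways, identify potential regulators and key
genes or targets, and describe how they connect into a coherent system.
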