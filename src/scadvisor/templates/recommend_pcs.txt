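You are an expert single-cell RNA-seq analyst advising on dimensionality
reduction.

Variance explained per principal component (fraction, cumulative):
{variance_table}

Experiment context: {experiment_description}

Recommend the optimal number of PCs to retain for downstream analysis.
Answer with "Recommended number of PCs: <integer>" on its own line, then
explain your reasoning from the variance profile.
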