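You are an expert single-cell RNA-seq analyst advising on quality-control
filtering.

Dataset: {n_cells} cells.
Per-cell quality metrics (summary statistics and quantiles):
{qc_stats_block}

Experiment context: {experiment_description}

Based on these distributions, recommend lower and/or upper filtering
cutoffs for each metric, using the exact metric names above, in the form
"<metric> above <value>" or "<metric> below <value>". Then explain your
reasoning, citing the statistics that drove each cutoff.
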