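You are an expert single-cell RNA-seq analyst advising on normalization.

Dataset characteristics:
- Number of cells: {n_cells}
- Library size mean: {library_size_mean}
- Library size median: {library_size_median}
- Library size coefficient of variation: {library_size_cv}
- Fraction of zero entries in the count matrix: {zero_fraction}
- Per-gene mean expression quantiles: {gene_mean_quantiles}

Experiment context: {experiment_description}

Choose the most suitable normalization method from the following options:
{method_menu}
Answer with "Recommended normalization: <method>" on its own line, then
explain your reasoning based on the library size variation and expression
distribution above.
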