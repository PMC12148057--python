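You are an expert in biological network curation.

The following summary describes pathways, regulators and key genes:
{enrichment_summary}

Extract the regulatory and pathway relationships as a directed network.
Output ONLY edge lines, one per line, in the exact format:
source|relation|target
Use gene, regulator or pathway names as nodes. Do not output anything
else.
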