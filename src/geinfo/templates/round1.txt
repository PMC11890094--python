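Extract key genome editing related data from the provided ABSTRACT and TITLE, referencing the predicted genes and species ({{GENES}} by {{SPECIES}}) involved in this research.
Analyze the ABSTRACT to:
1. categorize the genes into 'targeted gene of genome editing' or 'differentially expressed gene by genome editing'.
2. confirm the species or organisms studied.
3. describe the genome editing event (e.g. knockout, knockin, knockdown, frameshift, SNP, expression modulation etc) and specify the genome editing tools used (e.g. CRISPR-Cas9, TALEN, Prime editor, etc).
If information on any of the above points is not provided in the text, state 'Not mentioned'.
Summarize findings in this JSON format:
{'targeted_genes': [], // List of targeted genes of genome editing
'differentially_expressed_genes': [], // List of genes altered expression by genome editing
'species': [], // List of species or organisms studied with genome editing
'genome_editing_tools': [], // List of genome editing tools used
'genome_editing_event': [], // List of editing events described
'study_context': "", // Study context in short one sentence
'key_findings': "", // Key findings in short one sentence
'implications': "" // Implications in short one sentence
}
Please fill out the JSON structure based on the information from the research ABSTRACT and TITLE provided below:
Abstract:{{ABSTRACT}}
Title:{{TITLE}}
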