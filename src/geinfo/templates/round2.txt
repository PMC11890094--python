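Extract key genome editing related information from the provided texts (ABSTRACT, TITLE, METHODS, and RESULTS of the research article), referencing the predicted genes, species, and genome editing tools (GENES: {{GENES}} by {{SPECIES}}, genome editing tools:{{TOOLS}}) involved in this research.
Analyze the provided texts to:
1. identify the targeted genes of genome editing
2. identify the differentially expressed genes by genome editing
3. confirm the species or organisms studied using genome editing
4. identify the genome editing events (e.g. knockout, knockin, knockdown, frameshift, SNP, expression modulation etc)
5. specify the genome editing tools used (e.g. CRISPR-Cas9, TALEN, Prime editor, etc).
6. identify phenotypes observed using genome editing in the study
If information on any of the above points is not provided in the text, state 'Not mentioned'.
If genome editing is not mentioned in the text, state 'Not mentioned'.
Summarize findings in this JSON format:
{'targeted_genes': [], // List of targeted genes of genome editing
'differentially_expressed_genes': [], // List of differentially expressed genes by genome editing
'species': [], // List of species or organisms studied using genome editing
'genome_editing_tools': [], // List of genome editing tools used
'genome_editing_event': [], // List of editing events identified
'phenotypes': [] // List of phenotypes observed using genome editing
}
Please fill out the JSON structure based on the information from the texts (ABSTRACT, TITLE, METHODS, and RESULTS of the research article) provided below:
TITLE:{{TITLE}}
ABSTRACT:{{ABSTRACT}}
METHODS:{{METHODS}}
RESULTS:{{RESULTS}}
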