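{
  "template_version": "geo-bulk-seq-1.0",
  "study_fields": ["title", "summary", "overall design", "contributor", "supplementary file"],
  "study_mandatory": ["title", "summary", "overall design", "contributor"],
  "sample_fields": ["library name", "title", "organism", "source name", "molecule", "description"],
  "sample_mandatory": ["library name", "title", "organism", "source name"],
  "protocol_fields": ["growth protocol", "treatment protocol", "extract protocol", "library construction protocol", "library strategy", "data processing"],
  "protocol_mandatory": ["extract protocol", "data processing"],
  "organism_map": {
    "mouse": "Mus musculus",
    "rat": "Rattus norvegicus",
    "human-derived": "Homo sapiens",
    "patient": "Homo sapiens"
  },
  "molecule_map": {
    "bulk-transcriptomics": "total RNA",
    "bulk-metabolomics": "metabolite",
    "bulk-lipidomics": "lipid"
  }
}
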