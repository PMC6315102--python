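{
  "type": "object",
  "required": [
    "seed",
    "n_genes",
    "detected_count",
    "detected_fraction",
    "diel_count",
    "diel_fraction_of_detected",
    "diel_fraction_of_total",
    "light_dark_different_fraction",
    "cluster_sizes",
    "cluster_peak_hours",
    "network_edge_count",
    "antiphase_ortholog_fraction",
    "thresholds"
  ],
  "properties": {
    "seed": {"type": "integer"},
    "n_genes": {"type": "integer"},
    "detected_count": {"type": "integer"},
    "detected_fraction": {"type": "number"},
    "diel_count": {"type": "integer"},
    "diel_fraction_of_detected": {"type": "number"},
    "diel_fraction_of_total": {"type": "number"},
    "light_dark_different_fraction": {"type": "number"},
    "cluster_sizes": {"type": "array"},
    "cluster_peak_hours": {"type": "array"},
    "network_edge_count": {"type": "integer"},
    "antiphase_ortholog_fraction": {"type": "number"},
    "thresholds": {"type": "object"}
  }
}
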