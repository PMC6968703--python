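# Example selprof configuration file.
# Any key here can be overridden by the matching command-line flag.

# --- curation ---------------------------------------------------------
# Assay metrics to keep; all other records are filtered out.
metric_keep: [Ki]
# Restrict to publications whose Ki values came from one lab, to limit
# inter-assay bias. Omit (or null) to keep every publication.
# pmid_whitelist: ["25000001", "25000002", "25000003"]
# Replicate outlier rule: none | modified-z | trim-fraction.
outlier_rule: modified-z
outlier_zmax: 3.5
# Replicate averaging: arithmetic (on nM values) | geometric.
mean: arithmetic
# Zinc-binding-group filter; the default also matches sulfamates and
# sulfamides.
substructure_smarts: "[#16](=[OX1])(=[OX1])[NX3]"

# --- selectivity analysis ---------------------------------------------
on_target: "hCA IX"
off_target: "hCA II"
# Uncomment for double-selectivity mode (two on-targets, one off-target):
# secondary_on_target: "hCA XII"
s_score_cutoff: 70

# --- fingerprints & clustering ----------------------------------------
# keys (166 structural keys, default for clustering) | path (hashed
# 1024-bit linear-path fingerprint, default for Ti-SR correlation).
scheme: keys
height_ratio: 0.30
min_cluster_size: 5
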