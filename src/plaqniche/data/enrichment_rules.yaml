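# Default cell-type enrichment rules for deconvolution abundances.
# Each cell type lists one or more rules; a spot is enriched if any rule
# selects it. top_quantile keeps the top q fraction within each listed
# region group (ties inclusive); z_score keeps spots above mean + z sd of
# the pooled listed regions. Layer I is excluded for reference-atlas types.
fibroblast:
  - {regions: [gray matter, white matter], mode: top_quantile, q: 0.01, exclude: [layer I]}
  - {regions: [meninges], mode: top_quantile, q: 0.05}
pericyte:
  - {regions: [gray matter, white matter], mode: top_quantile, q: 0.01, exclude: [layer I]}
  - {regions: [meninges], mode: top_quantile, q: 0.05}
peripheral immune:
  - {regions: [gray matter, white matter], mode: top_quantile, q: 0.01, exclude: [layer I]}
  - {regions: [meninges], mode: top_quantile, q: 0.05}
smooth muscle cell:
  - {regions: [gray matter, white matter], mode: top_quantile, q: 0.01, exclude: [layer I]}
  - {regions: [meninges], mode: top_quantile, q: 0.05}
endothelial:
  - {regions: [gray matter, white matter], mode: top_quantile, q: 0.01, exclude: [layer I]}
  - {regions: [meninges], mode: top_quantile, q: 0.05}
microglia:
  - {regions: [gray matter, white matter], mode: top_quantile, q: 0.05, exclude: [layer I]}
astrocyte:
  - {regions: [gray matter, white matter], mode: top_quantile, q: 0.05, exclude: [layer I]}
interneuron:
  - {regions: [gray matter], mode: top_quantile, q: 0.05, exclude: [layer I]}
MYO16 EN:
  - {regions: [gray matter], mode: top_quantile, q: 0.01, exclude: [layer I]}
OPC:
  - {regions: [gray matter, white matter], mode: top_quantile, q: 0.05, exclude: [layer I]}
oligodendrocyte:
  - {regions: [white matter], mode: top_quantile, q: 0.30}
L2/3 EN:
  - {regions: [layers II-III], mode: top_quantile, q: 0.10}
L4 EN:
  - {regions: [layer IV], mode: top_quantile, q: 0.50}
L4/5 EN:
  - {regions: [layers IV-VI], mode: top_quantile, q: 0.15}
L5 EN:
  - {regions: [layers V-VI], mode: top_quantile, q: 0.05}
L5/6 EN:
  - {regions: [layers V-VI], mode: top_quantile, q: 0.05}
# microglia subclusters from a treatment-cohort atlas: sample-specific
# gray-matter mean + 3 sd threshold
microglia_cluster:
  - {regions: [gray matter], mode: z_score, z: 3.0}
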