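{
  "n_samples": 19,
  "dominant_barcodes": 53935,
  "total_barcodes": 61022,
  "mean_barcodes_per_sample": 3212,
  "note": "Published pooled barcode counts of the 19-sample cohort; per-sample absolute counts were not printed. PLC-16's scRNA proportion was printed as '79%' (low precision); stored as 79.00."
}
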