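{
 "peak_ids": [
  "chrS:910-1050",
  "chrS:856-906",
  "chrS:6950-7200",
  "chrS:1050-1150",
  "chrS:780-880",
  "chrS:16000-16400",
  "chrS:49950-50200"
 ],
 "labels": [
  "prom",
  "prom",
  "enhD",
  "exon",
  "exon",
  "empty",
  "enhD"
 ],
 "tss_hits": [
  [
   "GENEA"
  ],
  [
   "GENEB"
  ],
  [],
  [],
  [],
  [],
  []
 ],
 "label_counts": {
  "prom": 2,
  "enhD": 2,
  "exon": 2,
  "empty": 1,
  "total": 7
 },
 "gene_ids": [
  "GENEA",
  "GENEB"
 ],
 "prom_peak_ids": [
  "chrS:910-1050",
  "chrS:856-906"
 ],
 "enh_peak_ids": [
  "chrS:6950-7200",
  "chrS:49950-50200"
 ],
 "exon_peak_ids": [
  "chrS:1050-1150",
  "chrS:780-880"
 ],
 "cam": 0.5333333333333333,
 "kept_connections": [
  [
   "chrS:910-1050",
   "chrS:6950-7200",
   0.6,
   6095.0
  ]
 ],
 "GP": [
  [
   1,
   0
  ],
  [
   0,
   1
  ]
 ],
 "PE": [
  [
   0.6,
   0.0
  ],
  [
   0.0,
   0.0
  ]
 ],
 "GI": [
  [
   0.9801986733067553,
   0.0
  ],
  [
   0.0,
   0.9860975442628619
  ]
 ],
 "P": [
  [
   1.0,
   1.0,
   0.0
  ],
  [
   0.0,
   1.0,
   1.0
  ]
 ],
 "C": [
  [
   0.6,
   0.0,
   0.6
  ],
  [
   0.0,
   0.0,
   0.0
  ]
 ],
 "E": [
  [
   0.9801986733067553,
   0.0,
   0.0
  ],
  [
   0.0,
   0.9860975442628619,
   0.9860975442628619
  ]
 ],
 "gagam1": [
  [
   2.5801986733067555,
   1.0,
   0.6
  ],
  [
   0.0,
   1.986097544262862,
   1.986097544262862
  ]
 ],
 "gagam2": [
  [
   1.6,
   1.0,
   0.6
  ],
  [
   0.0,
   1.0,
   1.0
  ]
 ]
}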