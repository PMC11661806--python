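# Cell-culture transcriptional EC50 (KmT) survey for selected glucocorticoids.
# KmT for dexamethasone is absolute (nM); the other columns are ratios
# relative to dexamethasone.  Reference/documentation data only: nothing in
# the default computations reads this file.
schema_version: 1
cell_lines:
  - {cell_line: AZ-GR,       KmT_dex_nM: 9.55,  cortisol: 6.91, methylprednisolone: 3.16, prednisolone: 4.67, ref: 30}
  - {cell_line: HeLa,        KmT_dex_nM: 12,    cortisol: 11,   methylprednisolone: 3.33, prednisolone: 3.33, ref: 36}
  - {cell_line: A549,        KmT_dex_nM: 10,    cortisol: 15,   methylprednisolone: 4,    prednisolone: 7,    ref: 36}
  - {cell_line: HTC,         KmT_dex_nM: 4,     cortisol: 15,   methylprednisolone: 5,    prednisolone: 5,    ref: 36}
  - {cell_line: GR-LBD,      KmT_dex_nM: 0.154, cortisol: 30.9, methylprednisolone: 2.87, prednisolone: null, ref: 37}
  - {cell_line: PBMC,        KmT_dex_nM: 4.1,   cortisol: null, methylprednisolone: 3.36, prednisolone: 21,   ref: 38}
  - {cell_line: CCL-202,     KmT_dex_nM: 0.5,   cortisol: 20,   methylprednisolone: null, prednisolone: 10,   ref: 39}
  - {cell_line: GR/3xGRE,    KmT_dex_nM: 1.66,  cortisol: 27.5, methylprednisolone: null, prednisolone: null, ref: 40}
  - {cell_line: GR/MMTV,     KmT_dex_nM: 1.02,  cortisol: 58.9, methylprednisolone: null, prednisolone: null, ref: 40}
  - {cell_line: GR-LBD-b,    KmT_dex_nM: 0.83,  cortisol: 72.4, methylprednisolone: null, prednisolone: null, ref: 40}
  - {cell_line: "Clone #1",  KmT_dex_nM: 2.82,  cortisol: null, methylprednisolone: null, prednisolone: 5.37, ref: 28}
  - {cell_line: "Clone #5",  KmT_dex_nM: 5.89,  cortisol: null, methylprednisolone: null, prednisolone: 4.79, ref: 28}
  - {cell_line: "Clone #6",  KmT_dex_nM: 8.71,  cortisol: null, methylprednisolone: null, prednisolone: 3.98, ref: 28}
  - {cell_line: A549-b,      KmT_dex_nM: 1,     cortisol: 10,   methylprednisolone: null, prednisolone: null, ref: 28}
  - {cell_line: Hepatocytes, KmT_dex_nM: 10,    cortisol: null, methylprednisolone: null, prednisolone: null, ref: 31}
  - {cell_line: GR(WT),      KmT_dex_nM: 0.5,   cortisol: null, methylprednisolone: null, prednisolone: null, ref: 31}
  - {cell_line: GR(ER22),    KmT_dex_nM: 8,     cortisol: null, methylprednisolone: null, prednisolone: null, ref: 31}
  - {cell_line: AR42,        KmT_dex_nM: 10,    cortisol: null, methylprednisolone: null, prednisolone: null, ref: 31}
  - {cell_line: clinical,    KmT_dex_nM: null,  cortisol: 25,   methylprednisolone: 5,    prednisolone: 6.25, ref: 35}
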