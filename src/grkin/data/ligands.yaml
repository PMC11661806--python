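# Reference parameter sets for the glucocorticoid receptor trafficking model.
# Concentrations in nM, rates in min^-1.  This file is the single home of the
# published reference constants; code never repeats these literals.
schema_version: 1

# Shared kinetic constants (assumed glucocorticoid-independent; only the
# equilibrium constants Kc/Kn differ between ligands).
rate_constants:
  k1: 10.0      # RcG -> RcGt, cytoplasmic tight-binding conversion
  k2: 0.2       # RcGt -> RnGt, nuclear import (~5 min time constant)
  k3: 0.2       # RnGt -> RnGN, activation to the DNA-binding-competent form
  k4: 0.04      # RnGN -> Rn, ligand release / recycle (~25 min time constant)
  k5: 0.0017    # Rn -> Rc, nuclear export (~9.8 h time constant)
  k6: 1.0       # RnG -> RnGt, nuclear tight-binding conversion

Rtot: 1.0       # total receptor; pure scale factor

ligands:
  dexamethasone:
    Kc_nM: 5.0
    Kn_nM: 155.0
    KmT_nM: 5.0
    KmL_printed_nM: 0.00079
    source: model parameter table (DEX column) + representative affinity table
  cortisol:
    Kc_nM: 75.0
    Kn_nM: 1550.0
    KmT_nM: 50.0
    KmL_printed_nM: 0.0118
    source: model parameter table (cortisol column) + representative affinity table
  prednisolone: &prednisolone_affinity
    Kc_nM: 15.0
    Kn_nM: 465.0
    KmT_nM: 15.0
    KmL_printed_nM: 0.0044
    # 0.0044 is inconsistent with KmL scaling proportionally with Kc (which
    # predicts the methylprednisolone value below); suspected erratum, kept
    # as printed and flagged.
    KmL_suspected_erratum: true
    source: representative affinity table
  methylprednisolone:
    <<: *prednisolone_affinity
    KmL_printed_nM: 0.00236
    KmL_suspected_erratum: false
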