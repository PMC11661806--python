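# Pharmacokinetic parameter sets used by grkin.pk to turn dosing regimens
# into free plasma concentration profiles.
#
# PROVENANCE. The receptor-model source publication states only a handful of
# PK constants in its main text (dexamethasone oral bioavailability F = 0.59,
# free plasma fraction fu = 0.23 for dexamethasone and methylprednisolone,
# and the molecular weights 392.5 / 472.4 for DEX / DEX-phosphate); its full
# PK parameterisation lives in supplementary material that is not available
# here.  Every other number in this file is a literature-plausible
# placeholder chosen once so the module is runnable end-to-end, and is
# flagged `authoritative: false`.  Dose-regimen outputs (e.g. transcription
# quotients) computed from placeholder sets are structurally meaningful but
# not a reproduction of the publication's dose table.
#
# Units: volumes L, clearances L/min, first-order rates min^-1,
# molecular weights g/mol, concentrations nM.
schema_version: 1

drugs:
  dexamethasone:
    model: linear2c
    authoritative: false      # CL/V/Q/ka are placeholders; F, fu, MW are printed
    CL: 0.26
    Vc: 45.0
    Q: 0.2
    Vp: 40.0
    ka: 0.015
    F: 0.59                   # printed (oral bioavailability)
    fu: 0.23                  # printed (free plasma fraction)
    MW_drug: 392.5            # printed
    salts:
      phosphate:
        MW_salt: 472.4        # printed; IV DEX is given as the phosphate ester
    routes: [IV, oral]
    iv_salt_default: phosphate

  methylprednisolone:
    model: linear2c
    authoritative: false
    CL: 0.45
    Vc: 25.0
    Q: 0.3
    Vp: 55.0
    ka: 0.02
    F: 0.82
    fu: 0.23                  # printed (non-saturable binding, free fraction ~0.23)
    MW_drug: 374.5
    salts: {}
    routes: [IV, oral]
    iv_salt_default: null     # IV esters dosed as MP equivalents

  prednisone:
    model: prednisone_nonlinear
    authoritative: false
    routes: [oral]            # prodrug; oral only
    ka: 0.03
    F: 0.8
    MW_drug: 358.4
    MW_active: 360.4          # prednisolone
    V_pn: 45.0                # prednisone distribution volume
    V_pl: 45.0                # prednisolone distribution volume
    CL_pn_free: 0.5           # elimination clearance on free prednisone
    CL_pl_free: 1.3           # elimination clearance on free prednisolone
    CL_pn_to_pl: 8.0          # interconversion clearance, free prednisone -> prednisolone
    CL_pl_to_pn: 3.0          # interconversion clearance, free prednisolone -> prednisone
    first_pass_to_active: 0.9 # fraction of the absorbed dose converted to
                              # prednisolone during hepatic first pass
    fu_pn_albumin_ratio: 1.5  # bound/free ratio, linear (albumin-like) prednisone binding
    prednisolone_binding:
      Bmax_nM: 350.0          # transcortin (CBG) capacity, saturable
      Kd_nM: 60.0             # transcortin dissociation constant
      albumin_ratio: 2.0      # bound/free ratio of the linear component
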