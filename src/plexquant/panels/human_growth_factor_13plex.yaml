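# Panel Information for a LEGENDplex-style human growth factor 13-plex.
#
# Bead group A carries 6 analytes and group B carries 7; within a group
# the analyte IDs are ordered from low to high reporter-discrimination
# (APC) intensity. Start concentrations default to 50,000 pg/ml with a
# four-fold standard dilution. The analyte-name assignment to IDs is a
# plausible reconstruction of the commercial kit, not vendor data.
panel_name: Human Growth Factor Panel (13-plex)
std_dilution: 4.0
units: pg/ml
analytes:
  A:
    A4: {name: Angiopoietin-2, concentration: 50000.0}
    A5: {name: EGF, concentration: 50000.0}
    A6: {name: EPO, concentration: 50000.0}
    A7: {name: FGF-basic, concentration: 50000.0}
    A8: {name: G-CSF, concentration: 50000.0}
    A10: {name: GM-CSF, concentration: 50000.0}
  B:
    B2: {name: HGF, concentration: 50000.0}
    B3: {name: M-CSF, concentration: 50000.0}
    B4: {name: PDGF-AA, concentration: 50000.0}
    B5: {name: PDGF-BB, concentration: 50000.0}
    B6: {name: SCF, concentration: 50000.0}
    B7: {name: TGF-alpha, concentration: 50000.0}
    B9: {name: VEGF, concentration: 50000.0}
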