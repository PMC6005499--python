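# PTP1B open/closed-state distance criteria — PLACEHOLDER ASSUMPTIONS.
#
# The framework (centroid distances, open/closed references, majority vote)
# is what the package implements; these particular residue pairs and
# reference values are editable defaults built around the WPD-loop
# (Thr177-Pro185) geometry relative to the catalytic motif (Cys215) and the
# allosteric helices, NOT measured constants.  Replace them with values
# calibrated on your own reference structures before drawing conclusions.
criteria:
  - name: wpd_tip_to_catalytic_cys
    selection_a: [[181, CA]]       # Asp181, WPD-loop tip
    selection_b: [[215, CA]]       # Cys215, catalytic nucleophile
    open_ref: 15.0
    closed_ref: 10.0
    tolerance: 1.5
  - name: wpd_phe_to_catalytic_cys
    selection_a: [[180, CA]]       # Phe180
    selection_b: [[215, CA]]
    open_ref: 14.0
    closed_ref: 9.5
    tolerance: 1.5
  - name: wpd_to_alpha3
    selection_a: [[181, CA]]
    selection_b: [[193, CA]]       # Asn193, alpha3 helix
    open_ref: 12.0
    closed_ref: 15.0
    tolerance: 1.5
  - name: wpd_to_alpha6
    selection_a: [[181, CA]]
    selection_b: [[276, CA]]       # Glu276, alpha6 helix
    open_ref: 18.0
    closed_ref: 21.0
    tolerance: 1.5
  - name: alpha7_anchor
    selection_a: [[291, CA]]       # Trp291, alpha7 helix
    selection_b: [[280, CA]]       # Phe280, alpha6 helix
    open_ref: 10.0
    closed_ref: 13.0
    tolerance: 1.5
  - name: loop_gate
    selection_a: [[179, CA], [180, CA], [181, CA]]
    selection_b: [[214, CA], [215, CA], [216, CA]]
    open_ref: 14.5
    closed_ref: 10.0
    tolerance: 1.5
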