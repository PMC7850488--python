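# Canonical 18-parameter registry for multiparametric mutation scoring (MMS).
#
# Four general categories — protein-stability effects, mutation position,
# evolutionary conservation, change in amino-acid properties — plus the
# conserved-substitution indicator (the single sign -1 parameter) and
# codon/tRNA availability.  Each parameter is a 0/1 indicator; MMS is the
# signed sum.  Providers named here are resolved at evaluation time
# (see gldcscore.parameters).
parameters:
  # --- stability effects (CUPSAT-style ddG, kcal/mol) ---
  - name: ddg_very_destabilizing
    category: stability
    provider: ddg
    description: "ddG < -5.0 kcal/mol"
  - name: ddg_destabilizing
    category: stability
    provider: ddg
    description: "-5.0 <= ddG < -1.5 kcal/mol"
  - name: ddg_stabilizing
    category: stability
    provider: ddg
    description: "1.5 < ddG <= 5.0 kcal/mol (mirrored band)"
  - name: ddg_very_stabilizing
    category: stability
    provider: ddg
    description: "ddG > 5.0 kcal/mol (mirrored band)"
  # --- mutation position ---
  - name: pos_helix
    category: position
    provider: position
    description: "residue in an alpha helix"
  - name: pos_sheet
    category: position
    provider: position
    description: "residue in a beta sheet"
  - name: pos_dimer_interface
    category: position
    provider: position
    description: "residue in the dimerization interface"
  - name: pos_active_site
    category: position
    provider: position
    description: "residue within 5 A of the catalytic center (PLP-bound lysine / substrate)"
  # --- evolutionary conservation (ConSurf grades 1-9) ---
  - name: cons_grade_conserved
    category: conservation
    provider: consurf
    description: "ConSurf grade >= 7"
  - name: cons_grade_highly_conserved
    category: conservation
    provider: consurf
    description: "ConSurf grade >= 8"
  - name: cons_grade_maximal
    category: conservation
    provider: consurf
    description: "ConSurf grade == 9"
  - name: cons_functional_residue
    category: conservation
    provider: consurf
    description: "ConSurf-flagged functional residue (highly conserved and exposed)"
  # --- change in amino-acid properties ---
  - name: prop_proline_change
    category: property_change
    provider: properties
    description: "proline gained or lost"
  - name: prop_size_change
    category: property_change
    provider: properties
    description: "side-chain size class changes"
  - name: prop_polarity_change
    category: property_change
    provider: properties
    description: "polarity class changes"
  - name: prop_charge_change
    category: property_change
    provider: properties
    description: "formal charge class changes"
  # --- evolutionary tolerance of the exchange itself ---
  - name: conserved_substitution
    category: conservation
    provider: substitution_matrix
    sign: -1
    description: "exchange frequently tolerated through evolution (BLOSUM62 score >= 1); subtracts from the score"
  # --- translation ---
  - name: codon_rare
    category: translation
    provider: codon_usage
    description: "mutant codon is rare in the target species (poor tRNA availability)"
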