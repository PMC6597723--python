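# Selection config for rat CPR in the closed-form crystal structure
# numbering (PDB 1AMO, chain A).
#
# USER-EDITABLE EXAMPLE.  The residue ranges splitting the "FAD domain
# (including the connecting domain)" from the FMN domain are not a
# property of the file format — they are a modelling choice that
# depends on the construct, the rebuilt hinge residues and the
# deposition numbering.  Check them against your structure before use;
# nothing in the package depends on these particular values.
selections:
  fmn_domain:
    chain_id: A
    residue_ranges: [[66, 230]]      # flavodoxin-like FMN-binding domain
    atom_names: [CA]
  fad_domain:
    chain_id: A
    residue_ranges: [[231, 678]]     # connecting domain + FAD/NADPH domain
    atom_names: [CA]
  # cofactor rings default to the 15 fused-ring (iso)alloxazine atoms
  # N1 C2 O2 N3 C4 O4 C4A N5 C5A C6 C7 C8 C9 C9A N10; override the
  # atom list here if your chemical-component dialect differs.
  fad_ring:
    residue_names: [FAD]
    atom_names: [N1, C2, O2, N3, C4, O4, C4A, N5, C5A, C6, C7, C8, C9, C9A, N10]
  fmn_ring:
    residue_names: [FMN]
    atom_names: [N1, C2, O2, N3, C4, O4, C4A, N5, C5A, C6, C7, C8, C9, C9A, N10]
  # heme of the partner monooxygenase in a CPR complex structure: all
  # heavy atoms of the HEM residue, on the partner chain.
  heme:
    residue_names: [HEM]
    chain_id: B
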