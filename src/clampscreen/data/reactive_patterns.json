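{
  "version": "1.0",
  "description": "Minimal reactive / covalent-warhead substructure screen (SMARTS). Swappable: pass any file of the same shape to FilterPolicy.from_files or replace this one.",
  "patterns": {
    "acyl_halide": "[CX3](=O)[F,Cl,Br,I]",
    "sulfonyl_halide": "[SX4](=O)(=O)[F,Cl,Br,I]",
    "alkyl_halide": "[CX4][Cl,Br,I]",
    "aldehyde": "[CX3H1](=O)[#6]",
    "anhydride": "[CX3](=O)O[CX3](=O)",
    "epoxide_aziridine": "[OX2r3,NX3r3]1[CX4r3][CX4r3]1",
    "isocyanate_isothiocyanate": "[NX2]=C=[O,S]",
    "michael_acceptor_vinyl_ketone": "[CX3]=[CX3][CX3](=O)[#6]",
    "acrylamide": "[CX3]=[CX3][CX3](=O)[NX3]",
    "vinyl_sulfone": "[CX3]=[CX3][SX4](=O)(=O)",
    "diazo": "[#6]=[N+]=[N-]",
    "azide": "[NX2]=[N+]=[N-]",
    "peroxide": "[OX2][OX2]",
    "thiol": "[#6][SX2H]",
    "boronic_acid": "[BX3]([OX2H])[OX2H]",
    "imine_of_aldehyde": "[CX3H1]=[NX2][#6]"
  }
}
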