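# Donor/acceptor role table for hydrogen-bond detection at biological pH.
# backbone entries apply to every standard residue; proline's amide nitrogen
# carries no hydrogen and is excluded from donors. Hydroxyl oxygens are both
# donor and acceptor. Asp/Glu are modelled deprotonated (acceptors only),
# Lys/Arg protonated (donors), His neutral with the NE2-H tautomer.
backbone:
  donors:
    - atom: N
      exclude_residues: [PRO]
  acceptors:
    - atom: O
      antecedents: [C]
    - atom: OXT
      antecedents: [C]
sidechain:
  SER:
    OG: {roles: [donor, acceptor], antecedents: [CB]}
  THR:
    OG1: {roles: [donor, acceptor], antecedents: [CB]}
  TYR:
    OH: {roles: [donor, acceptor], antecedents: [CZ]}
  ASP:
    OD1: {roles: [acceptor], antecedents: [CG]}
    OD2: {roles: [acceptor], antecedents: [CG]}
  GLU:
    OE1: {roles: [acceptor], antecedents: [CD]}
    OE2: {roles: [acceptor], antecedents: [CD]}
  ASN:
    OD1: {roles: [acceptor], antecedents: [CG]}
    ND2: {roles: [donor]}
  GLN:
    OE1: {roles: [acceptor], antecedents: [CD]}
    NE2: {roles: [donor]}
  LYS:
    NZ: {roles: [donor]}
  ARG:
    NE: {roles: [donor]}
    NH1: {roles: [donor]}
    NH2: {roles: [donor]}
  HIS:
    ND1: {roles: [acceptor], antecedents: [CG, CE1]}
    NE2: {roles: [donor]}
  TRP:
    NE1: {roles: [donor]}
  MET:
    SD: {roles: [acceptor], antecedents: [CG, CE]}
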