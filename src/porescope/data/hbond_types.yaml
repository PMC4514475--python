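# Donor/acceptor typing by residue name.  Donors are [heavy atom, hydrogen]
# pairs; acceptors are heavy atoms.  `protein_default` applies to every
# protein residue (backbone amide donor, carbonyl acceptor) and is merged
# with the per-residue side-chain entries below.  Edit or extend freely.
protein_default:
  donors: [[N, H], [N, HN]]
  acceptors: [O]
water:
  donors: [[O, H1], [O, H2]]
  acceptors: [O]
residues:
  SER:
    donors: [[OG, HG], [OG, HG1]]
    acceptors: [OG]
  THR:
    donors: [[OG1, HG1]]
    acceptors: [OG1]
  TYR:
    donors: [[OH, HH]]
    acceptors: [OH]
  ASN:
    donors: [[ND2, HD21], [ND2, HD22]]
    acceptors: [OD1]
  GLN:
    donors: [[NE2, HE21], [NE2, HE22]]
    acceptors: [OE1]
  ASP:
    donors: []
    acceptors: [OD1, OD2]
  GLU:
    donors: []
    acceptors: [OE1, OE2]
  LYS:
    donors: [[NZ, HZ1], [NZ, HZ2], [NZ, HZ3]]
    acceptors: []
  ARG:
    donors: [[NE, HE], [NH1, HH11], [NH1, HH12], [NH2, HH21], [NH2, HH22]]
    acceptors: []
  HIS:
    donors: [[ND1, HD1], [NE2, HE2]]
    acceptors: [ND1, NE2]
  TRP:
    donors: [[NE1, HE1]]
    acceptors: []
  CYS:
    donors: [[SG, HG]]
    acceptors: [SG]
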