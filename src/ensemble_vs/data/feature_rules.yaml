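# Pharmacophore feature typing rules (SMARTS).
#
# point_features place one feature on each matched atom; group_features place
# one feature at the centroid of all atoms of each match. Hydrophobic (HYD)
# and aromatic-ring (RA) features are perceived algorithmically (contiguous
# apolar-carbon groups and aromatic rings) and are not listed here.
# Protonation states follow physiological-pH conventions: carboxylic acids
# count as negative ionizable, aliphatic amines as positive ionizable.
point_features:
  HBD:
    - "[N;!H0;v3;+0]"
    - "[N;!H0;+1]"
    - "[OX2;H1;+0]"
    - "[SX2;H1;+0]"
    - "[n;H1;+0]"
  HBA:
    - "[OX2;H1;+0]"
    - "[OX2;H0;+0]"
    - "[OX1;+0]"
    - "[OX1-]"
    - "[NX3;H0;v3;+0;!$(N=*);!$(N[a]);!$(NC=O)]"
    - "[NX2;H0;+0]"
    - "[nX2;H0;+0]"
group_features:
  NI:
    - "[CX3](=O)[O-]"
    - "[CX3](=O)[OX2H1]"
    - "[SX4](=O)(=O)[O-]"
    - "[SX4](=O)(=O)[OX2H1]"
  PI:
    - "[NX4+]"
    - "[NX3;H2,H1;+0;!$(NC=O);!$(N[a]);!$(N=*);!$(NS)]"
    - "[NX3;H0;+0;$(N(C)(C)C);!$(NC=O);!$(N[a])]"
    - "NC(=[NX2])N"
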