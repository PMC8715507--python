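# Default coupling topologies around the Calpha-Cbeta bond.
# delta_theta follows the ideal tetrahedral convention (theta = chi1 + delta_theta,
# phases 0/+120/-120).  Alpha-side offsets: NP 0, CP +120, HA -120 relative to the
# chi1-defining nitrogen.  Beta-side branch assignments relative to the
# chi1-defining gamma atom (CG1 for Val/Ile, CG for Leu):
#   VAL: CG1 0, CG2 +120, HB -120
#   LEU: CG 0, HB3 +120, HB2 -120
#   ILE: CG1 0, HB +120, CG2 -120
# Override per coupling with ResidueTopology.with_overrides or a user table.
residue_type,coupling_id,nucleus_x,nucleus_y,delta_theta
VAL,HA-HB,HA,HB,120
VAL,HA-CG1,HA,CG1,-120
VAL,HA-CG2,HA,CG2,0
VAL,CP-HB,CP,HB,0
VAL,CP-CG1,CP,CG1,120
VAL,CP-CG2,CP,CG2,-120
VAL,NP-HB,NP,HB,-120
VAL,NP-CG1,NP,CG1,0
VAL,NP-CG2,NP,CG2,120
LEU,HA-HB2,HA,HB2,120
LEU,HA-HB3,HA,HB3,0
LEU,HA-CG,HA,CG,-120
LEU,CP-HB2,CP,HB2,0
LEU,CP-HB3,CP,HB3,-120
LEU,CP-CG,CP,CG,120
LEU,NP-HB2,NP,HB2,-120
LEU,NP-HB3,NP,HB3,120
LEU,NP-CG,NP,CG,0
ILE,HA-HB,HA,HB,0
ILE,HA-CG1,HA,CG1,-120
ILE,HA-CG2,HA,CG2,120
ILE,CP-HB,CP,HB,-120
ILE,CP-CG1,CP,CG1,120
ILE,CP-CG2,CP,CG2,0
ILE,NP-HB,NP,HB,120
ILE,NP-CG1,NP,CG1,0
ILE,NP-CG2,NP,CG2,-120
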