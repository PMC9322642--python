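# Pharmacophore atom-class definitions used by the reference shape scorer.
# Each class is a list of SMARTS patterns; an atom belongs to a class if it
# matches any pattern. Bump `version` on any change: descriptors computed
# with different versions must not be compared.
version: 1
classes:
  donor:
    - "[N!H0;v3,v4&+1]"
    - "[OX2H]"
    - "[SX2H]"
    - "[nH]"
  acceptor:
    - "[OX1]"
    - "[OX2;H0;!$(O=*)]"
    - "[O;-]"
    - "[NX3;H0;v3;!$(N-*=[O,N,S])]"
    - "[nX2;H0]"
    - "[NX1]#*"
  aromatic:
    - "a"
  hydrophobe:
    - "[CX4;!$(C[#7,#8,#9,#16,#17,#35,#53])]"
    - "[c]"
    - "[S;X2;H0]"
    - "[Cl,Br,I]"
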