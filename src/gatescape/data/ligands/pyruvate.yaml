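# Pyruvate ligand chemistry (package-local atom naming: carboxylate C1
# with O1/O2, keto C2 with O3, methyl C3).
res_name: PYR
donors: []
acceptors: [O1, O2, O3]
charged_groups:
  - name: carboxylate
    atoms: [O1, O2]
    sign: -1
rings: []
apolar: [C3]
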