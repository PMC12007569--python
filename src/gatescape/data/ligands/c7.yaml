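# Cyanoacrylate-class inhibitor (C7-like) chemistry, package-local atom
# naming: carboxylate C1/O1/O2, cyano C2/N1, acrylate C3, furyl ring
# (O3, C4-C7), nitrophenyl ring (C8-C13) with nitro N2/O4/O5.
res_name: C7A
donors: []
acceptors: [O1, O2, N1, O4, O5]
charged_groups:
  - name: carboxylate
    atoms: [O1, O2]
    sign: -1
rings:
  - [O3, C4, C5, C6, C7]
  - [C8, C9, C10, C11, C12, C13]
apolar: [C3, C4, C5, C6, C7, C8, C9, C10, C11, C12, C13]
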