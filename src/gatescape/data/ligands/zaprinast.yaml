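# Zaprinast-like chemistry, package-local atom naming: fused
# triazolopyrimidinone (purinone-like) core rings, carbonyl O1, ring NH
# donors N1/N4, propoxyphenyl ring (C7-C12) with ether O2 and propyl
# C13-C15.
res_name: ZAP
donors: [N1, N4]
acceptors: [O1, O2, N2, N3, N5]
charged_groups: []
rings:
  - [C1, N1, C2, N2, C3, C4]
  - [N3, N4, N5, C3, C4]
  - [C7, C8, C9, C10, C11, C12]
apolar: [C13, C14, C15, C7, C8, C9, C10, C11, C12]
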