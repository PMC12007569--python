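# Thiazolidinedione-class (mitoglitazone-like) chemistry, package-local
# atom naming: thiazolidinedione ring (S1, C1-C3, N1) with carbonyls
# O1/O2 and ring NH donor N1, central phenyl (C5-C10), pyridyl ring
# (C11-C15, N2), linker carbons C4/C16-C17.
res_name: MGZ
donors: [N1]
acceptors: [O1, O2, N2, O3]
charged_groups: []
rings:
  - [S1, C1, N1, C2, C3]
  - [C5, C6, C7, C8, C9, C10]
  - [C11, C12, C13, C14, C15, N2]
apolar: [C4, C16, C17, C5, C6, C7, C8, C9, C10]
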