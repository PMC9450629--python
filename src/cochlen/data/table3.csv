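# Per-case digitized-ruler readings (mm), vestibule (R1) towards apex (Rx).
# DNM = no further segment placed for that case.
# Original comma-decimal source strings, kept verbatim for auditability:
#   R1: 2,00 2,00 2,00 2,00 2,00 2,00
#   R2: 2,00 2,00 2,00 2,00 2,00 2,00
#   R3: 2,00 2,00 2,00 2,00 2,00 2,00
#   R4: 2,00 2,00 2,00 2,00 2,00 2,00
#   R5: 2,00 2,00 2,00 2,00 2,00 2,00
#   R6: 2,00 2,00 2,00 2,00 2,00 2,00
#   R7: 2,00 2,00 2,00 2,00 2,00 1,50
#   R8: 2,00 2,00 2,00 2,00 2,00 1,50
#   R9: 2,00 1,00 2,00 2,00 2,00 1,00
#   R10: 1,50 1,00 1,50 1,50 2,00 1,00
#   R11: 1,50 1,00 1,50 1,50 2,00 DNM
#   R12: 1,00 DNM 1,50 1,00 2,00 DNM
#   R13: 1,00 DNM 1,00 DNM 1,50 DNM
#   R14: DNM DNM DNM DNM 1,00 DNM
#   length (mm): 23,00 19,00 23,50 22,00 26,50 17,00
label,case1,case2,case3,case4,case5,case6
R1,2.0,2.0,2.0,2.0,2.0,2.0
R2,2.0,2.0,2.0,2.0,2.0,2.0
R3,2.0,2.0,2.0,2.0,2.0,2.0
R4,2.0,2.0,2.0,2.0,2.0,2.0
R5,2.0,2.0,2.0,2.0,2.0,2.0
R6,2.0,2.0,2.0,2.0,2.0,2.0
R7,2.0,2.0,2.0,2.0,2.0,1.5
R8,2.0,2.0,2.0,2.0,2.0,1.5
R9,2.0,1.0,2.0,2.0,2.0,1.0
R10,1.5,1.0,1.5,1.5,2.0,1.0
R11,1.5,1.0,1.5,1.5,2.0,DNM
R12,1.0,DNM,1.5,1.0,2.0,DNM
R13,1.0,DNM,1.0,DNM,1.5,DNM
R14,DNM,DNM,DNM,DNM,1.0,DNM
total,23.0,19.0,23.5,22.0,26.5,17.0
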