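# Five-reaction multiplex typing panel for KIR3DL1/KIR3DS1 allele subtypes.
#
# Primer sequences and expected amplicon sizes are transcribed bit-exactly
# from the published primer table; per-reaction thermocycling metadata is
# carried verbatim but is inert (never used in any computation).
#
# Discrepancy note: the protocol narrative twice describes the internal
# control band as 650 bp, while the primer table prints 607 bp for the
# HLA-DR pair.  The primer-table value (607) is recorded here; the true
# product size is not resolvable from the source material.
notes: >
  Internal control product recorded as 607 bp per the primer table; the
  protocol narrative says 650 bp.  Metadata fields are inert.
control:
  forward: {name: FDRA-360, seq: GAGGTAACTGTGCTCACGAACAGC}
  reverse: {name: RDRA-633, seq: CACGTTCTCTGTAGTCTCTGGG}
  expected_size: 607
reactions:
  - id: R1
    targets: ["NULL"]
    forward: {name: ConsF, seq: ATCCTGTGCGCTGCTGAGCTGAG}
    reverse: {name: 193G-R, seq: CATGGAAGATGGGAATGTGGATTCC}
    expected_sizes: {KIR3DL1: 2019}
    metadata: {annealing_c: 66.9, extension_min: "3:30", cycles: 30,
               primer_um: 0.795, control_um: 0.040}
  - id: R2
    targets: ["LOW1"]
    forward: {name: 202A2-F, seq: CAATTTCATGCTATACAAAGAAGACA}
    reverse: {name: 607T-R, seq: GGGRGCTGACAACTGATAGGA}
    expected_sizes: {KIR3DL1: 1573}
    metadata: {annealing_c: 65.6, extension_min: "3:30", cycles: 30,
               primer_um: 0.795, control_um: 0.040}
  - id: R3
    targets: ["HIGH1"]
    forward: {name: 202A3-F, seq: GCTATACAAAGAAGACAGAATCCACA}
    reverse: {name: 607C-R, seq: GGGAGCTGACAACTGATAGGG}
    expected_sizes: {KIR3DL1: 1573}
    metadata: {annealing_c: 67.0, extension_min: "3:45", cycles: 35,
               primer_um: 0.795, control_um: 0.173}
  - id: R4
    targets: ["HIGH2", "S1"]
    forward: {name: 202G-F, seq: CAAAGAAGACAGAATCCACG}
    reverse: {name: 607C-R, seq: GGGAGCTGACAACTGATAGGG}
    expected_sizes: {KIR3DL1: 1573, KIR3DS1: 1933}
    metadata: {annealing_c: 64.2, extension_min: "4:00", cycles: 35,
               primer_um: 0.795, control_um: 0.040}
  - id: R5
    targets: ["LOW2"]
    forward: {name: int6-F, seq: CAGAGATCTGTGCCAGC}
    reverse: {name: 1021/22-S-R, seq: GAGGTCCCAATCAGAACG}
    expected_sizes: {KIR3DL1: 1408}
    metadata: {annealing_c: 64.2, extension_min: "3:45", cycles: 35,
               primer_um: 0.795, control_um: 0.086}
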