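# A single NOT mapping module with an amplifier and a fluorescence
# reporter, at 1X = 10^4 nM.  Run with e.g.
#   domaincode simulate examples/not_stage.yaml --input 0 --out out/
name: not_stage
unit_conc: 10000
params: {k_bind: 3.0e-4, k_unbind: 0.1126}
inputs: {A0: 0}
outputs: [Z]
gates:
  - {type: mapping, id: M.Y, inputs: [A0], output: Y, function: NOT}
  - {type: amplifier, id: AMP.Y, input: Y, output: Z}
  - {type: reporter, id: REP.Z, input: Z}
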