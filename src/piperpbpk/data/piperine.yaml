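# Piperine model input parameters.
# Physicochemistry and binding from published measurements; absorption
# (fu_gut, Qgut, Peff) and distribution (Vss, mechanistic method 2) are
# platform-predicted input values; CLint is the pooled mean of six
# microsomal substrate-depletion estimates; Kapp/kinact/fu_mic are the
# CYP3A4 mechanism-based-inactivation constants.
name: piperine
mw: 285.34
logp: 1.86
compound_type: monoprotic base
pka: 12.22
bp_ratio: 0.63
fu_plasma: 0.03
papp_caco2: 47.8
peff_man: 5.13
solubility: 0.004
fu_gut: 0.0211
qgut: 15.4
vss: 0.826
clint_hlm: 24.2
kapp: 6.74
kinact: 0.558
fu_mic: 0.863
dose_mg: 20.0
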