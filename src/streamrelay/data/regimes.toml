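# Canned (secretion, degradation) presets that realize the three collective
# migration regimes under the example parameter set, all at the same fast
# degradation rate (the regime is selected by the relay strength alone).
# Repository choices: representative points, one per regime, used in tests
# and docs.

[uncorrelated]
beta = 0.02
kmax = 40.0

[streaming]
beta = 0.07
kmax = 40.0

[clumping]
beta = 0.3
kmax = 40.0
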