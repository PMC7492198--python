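# Dehiscence-area sweep: AC/BC threshold changes and the air-bone gap
# for superior semicircular canal dehiscence, vs the intact healthy ear.
kind: sscd_sweep
areas: [0.1, 0.5, 1.0, 3.0, 6.0, no_imp]
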