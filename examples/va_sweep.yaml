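# Vestibular-aqueduct size sweep (intact canal): the narrow duct's
# diameter is scaled between half and double its nominal 0.3 mm.
kind: va_sweep
scales: [0.5, 0.75, 1.5, 2.0]
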