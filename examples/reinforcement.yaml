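# Window reinforcement: stiffen the oval and round windows 100x in an ear
# with a 3 mm^2 dehiscence, referenced to the normal healthy ear.
kind: reinforcement
ow_factor: 100
rw_factor: 100
sscd_area_mm2: 3.0
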