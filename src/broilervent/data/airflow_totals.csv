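location,measured,simulated,units
inlet_total_5fans,175908,171397,m3 h-1
inlet_total_14fans,185912,200923,m3 h-1
cooling_pad_total_14fans,263134,278990,m3 h-1
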