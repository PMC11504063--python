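location,measured,simulated,units
Zone 1,0.25,0.29,m s-1
Zone 2,0.50,0.51,m s-1
Zone 3,0.68,0.90,m s-1
Zone 4,0.33,0.28,m s-1
Zone 5,0.57,0.62,m s-1
Zone 6,0.84,0.90,m s-1
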