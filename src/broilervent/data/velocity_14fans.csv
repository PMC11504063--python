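location,measured,simulated,units
Zone 1,1.38,1.06,m s-1
Zone 2,1.98,1.77,m s-1
Zone 3,2.00,2.04,m s-1
Zone 4,1.33,1.01,m s-1
Zone 5,1.82,1.77,m s-1
Zone 6,2.11,2.00,m s-1
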