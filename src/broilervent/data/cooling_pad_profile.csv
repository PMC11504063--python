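location,measured,simulated,units
C1 (14 fans),4995,5143,m3 h-1 m-1
C2 (14 fans),5995,4948,m3 h-1 m-1
C3 (14 fans),6230,6830,m3 h-1 m-1
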