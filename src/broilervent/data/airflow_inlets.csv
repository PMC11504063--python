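location,measured,simulated,units
A1 (5 fans),1763,2558,m3 h-1
A2 (5 fans),3696,2704,m3 h-1
A3 (5 fans),3750,2880,m3 h-1
A4 (5 fans),2664,2855,m3 h-1
A1 (14 fans),2711,2029,m3 h-1
A2 (14 fans),3565,3453,m3 h-1
A3 (14 fans),3361,3765,m3 h-1
A4 (14 fans),3666,3961,m3 h-1
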