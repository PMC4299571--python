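intervention,arms_covered,start_up,annual_implementation,annual_maintenance,annual_external,printed_trial_total
CI,2,362083,2068997,27250,120067,5348791
FI,2,362860,2026811,25328,272017,5592212
FICI,1,362472,2047904,26289,196042,5470501
FICI_2ARM,2,724943,4095808,52578,392084,10941002
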