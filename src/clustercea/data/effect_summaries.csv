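intervention,quantity,mean,lo,hi
CI,baby_or,0.873,0.774,0.982
CI,mother_or,0.957,0.494,1.657
CI,babies_saved,772,109,1384
CI,mothers_saved,18,-270,210
CI,dalys_averted,67361,8808,121508
FI,baby_or,0.954,0.846,1.070
FI,mother_or,1.228,0.652,2.135
FI,babies_saved,291,-439,974
FI,mothers_saved,-97,-480,148
FI,dalys_averted,19901,-44769,80586
FICI,baby_or,0.841,0.707,0.992
FICI,mother_or,1.287,0.488,2.839
FICI,babies_saved,475,23,880
FICI,mothers_saved,-62,-397,112
FICI,dalys_averted,37590,-4642,74618
FICI_2ARM,babies_saved,951,46,1760
FICI_2ARM,mothers_saved,-124,-793,223
FICI_2ARM,dalys_averted,75180,-9284,149236
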