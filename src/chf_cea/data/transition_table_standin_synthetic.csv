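from_class,toI_noh,toI_h,toII_noh,toII_h,toIII_noh,toIII_h,toIV_noh,toIV_h,cv_death,noncv_death
I,0.700,0.020,0.170,0.015,0.030,0.005,0.004,0.001,0.035,0.020
II,0.080,0.005,0.560,0.070,0.130,0.040,0.020,0.010,0.055,0.030
III,0.010,0.002,0.100,0.018,0.430,0.130,0.090,0.060,0.110,0.050
IV,0.010,0.002,0.100,0.018,0.430,0.130,0.090,0.060,0.110,0.050
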