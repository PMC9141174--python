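site,date,inversion_aod,observation_aod
SONET_Shanghai,2016-05-01,0.610,0.785
SONET_Shanghai,2016-05-03,0.792,0.890
SONET_Shanghai,2016-05-04,0.500,0.449
SONET_Shanghai,2016-05-12,0.375,0.304
SONET_Shanghai,2016-05-15,0.400,0.551
SONET_Shanghai,2016-05-16,0.917,0.346
SONET_Shanghai,2016-05-17,0.400,0.222
SONET_Shanghai,2016-05-24,1.170,1.194
SONET_Shanghai,2016-05-25,1.246,0.951
SONET_Shanghai,2016-06-06,0.720,1.153
SONET_Zhoushan,2016-04-30,0.808,0.464
SONET_Zhoushan,2016-05-01,0.730,0.474
SONET_Zhoushan,2016-05-03,0.320,0.314
SONET_Zhoushan,2016-05-04,0.700,0.775
SONET_Zhoushan,2016-05-11,1.170,0.815
SONET_Zhoushan,2016-05-12,0.563,0.534
SONET_Zhoushan,2016-05-16,0.200,0.218
SONET_Zhoushan,2016-05-17,0.150,0.154
SONET_Zhoushan,2016-05-18,0.200,0.199
SONET_Zhoushan,2016-05-24,1.000,1.022
SONET_Zhoushan,2016-06-06,0.350,0.360
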