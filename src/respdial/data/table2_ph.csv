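qb_ml_min,inlet_pco2_target,qd_ml_min,side,ph_mean,ph_sd,n_lt_3,significant
18.7,50,2.2,pre,7.146,0.015,True,False
18.7,50,2.2,post,7.151,0.004,True,False
11,50,3,pre,7.207,0.030,False,True
11,50,3,post,7.230,0.030,False,True
11,100,3,pre,7.077,0.003,False,False
11,100,3,post,7.102,0.010,False,False
18.7,50,3,pre,7.144,0.013,False,True
18.7,50,3,post,7.157,0.008,False,True
11,50,8,pre,7.189,0.024,False,True
11,50,8,post,7.233,0.018,False,True
11,100,8,pre,7.084,0.008,False,True
11,100,8,post,7.130,0.004,False,True
18.7,50,8,pre,7.145,0.003,False,True
18.7,50,8,post,7.174,0.002,False,True
11,50,11.5,pre,7.197,0.028,False,False
11,50,11.5,post,7.240,0.023,False,False
11,100,11.5,pre,7.072,0.013,False,True
11,100,11.5,post,7.125,0.011,False,True
18.7,50,11.5,pre,7.143,0.003,False,True
18.7,50,11.5,post,7.179,0.005,False,True
11,50,16,pre,7.181,0.022,False,False
11,50,16,post,7.252,0.023,False,False
11,100,16,pre,7.086,0.012,False,True
11,100,16,post,7.148,0.006,False,True
18.7,50,16,pre,7.148,0.019,False,True
18.7,50,16,post,7.181,0.007,False,True
11,50,20,pre,7.191,0.024,False,True
11,50,20,post,7.259,0.027,False,True
11,100,20,pre,7.083,0.012,False,True
11,100,20,post,7.148,0.004,False,True
11,100,24,pre,7.070,0.008,False,True
11,100,24,post,7.151,0.012,False,True
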