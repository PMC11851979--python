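condition_id,n,lp,up,above
1,1000,0.9392,1.0325,0.6260
1,2500,0.9618,1.0197,0.8640
1,5000,0.9726,1.0155,0.9720
1,10000,0.9813,1.0124,0.9950
1,20000,0.9882,1.0084,0.9980
19,1000,0.7884,1.1462,0.2780
19,2500,0.8928,1.0977,0.3110
19,5000,0.9197,1.0632,0.4210
19,10000,0.9454,1.0480,0.4820
19,20000,0.9620,1.0337,0.5870
19,25000,0.9649,1.0276,0.7110
19,30000,0.9667,1.0272,0.7950
19,35000,0.9714,1.0248,0.8000
19,40000,0.9706,1.0221,0.8630
19,45000,0.9748,1.0221,0.8910
19,50000,0.9765,1.0213,0.9120
26,1000,0.4269,1.3220,0.1710
26,2500,0.6477,1.1837,0.0880
26,5000,0.7760,1.1413,0.1250
26,10000,0.8486,1.0929,0.1830
26,20000,0.8885,1.0710,0.4050
26,25000,0.9023,1.0553,0.6430
26,30000,0.9111,1.0568,0.7010
26,35000,0.9090,1.0439,0.7420
26,40000,0.9258,1.0437,0.7650
26,45000,0.9208,1.0424,0.8210
26,50000,0.9312,1.0410,0.8350
38,1000,0.9590,1.0173,0.5810
38,2500,0.9750,1.0110,0.8860
38,5000,0.9815,1.0094,0.9740
38,10000,0.9882,1.0064,0.9940
38,20000,0.9924,1.0052,0.9990
98,1000,0.1774,1.4159,0.3970
98,2500,0.5197,1.2486,0.3190
98,5000,0.6566,1.1807,0.2350
98,10000,0.7479,1.1430,0.2050
98,20000,0.8455,1.0994,0.2250
98,25000,0.8424,1.0679,0.1660
98,30000,0.8538,1.0578,0.1460
98,35000,0.8593,1.0480,0.1500
98,40000,0.8808,1.0488,0.1400
98,45000,0.8697,1.0457,0.1670
98,50000,0.8761,1.0463,0.1540
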