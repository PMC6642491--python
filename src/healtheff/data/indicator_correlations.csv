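code,PPP,EXP,NC,NTHC,DA,DTH,LDT,RNT,BED,NV,NI,UB,ADH
PPP,1.000,0.561,0.403,0.716,0.337,0.169,0.216,0.195,0.492,0.223,-0.215,-0.209,0.207
EXP,0.561,1.000,0.355,0.703,0.294,-0.384,-0.143,-0.196,-0.117,-0.204,-0.136,-0.216,-0.204
NC,0.403,0.355,1.000,0.532,0.741,-0.185,0.215,0.039,0.131,-0.229,-0.024,-0.233,-0.200
NTHC,0.716,0.703,0.532,1.000,0.320,0.041,-0.062,-0.210,0.098,0.187,-0.274,-0.314,0.150
DA,0.337,0.294,0.741,0.320,1.000,-0.197,0.166,0.034,0.113,-0.325,0.078,-0.135,-0.289
DTH,0.169,-0.384,-0.185,0.041,-0.197,1.000,-0.037,0.039,0.351,0.660,-0.040,0.090,0.587
LDT,0.216,-0.143,0.215,-0.062,0.166,-0.037,1.000,0.887,0.598,-0.215,0.111,-0.023,-0.141
RNT,0.195,-0.196,0.039,-0.210,0.034,0.039,0.887,1.000,0.636,-0.185,0.246,0.080,-0.130
BED,0.492,-0.117,0.131,0.098,0.113,0.351,0.598,0.636,1.000,0.262,0.160,0.164,0.319
NV,0.223,-0.204,-0.229,0.187,-0.325,0.660,-0.215,-0.185,0.262,1.000,-0.103,0.294,0.958
NI,-0.215,-0.136,-0.024,-0.274,0.078,-0.040,0.111,0.246,0.160,-0.103,1.000,0.774,-0.115
UB,-0.209,-0.216,-0.233,-0.314,-0.135,0.090,-0.023,0.080,0.164,0.294,0.774,1.000,0.326
ADH,0.207,-0.204,-0.200,0.150,-0.289,0.587,-0.141,-0.130,0.319,0.958,-0.115,0.326,1.000
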