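no,compound,rt_min,std_amf,std_armf,std_n,real_amf,real_armf,s1_n,s2_n,s3_n
1,Naphthalene,5.19,945,956,3,895,928,3,3,3
2,Dichlorvos,5.41,835,884,3,796,826,2,3,3
3,2-methylnaphthalene,5.68,867,900,3,893,928,3,3,3
4,1-methylnaphthalene,5.77,922,931,3,903,924,3,3,2
5,Acenaphthylene,6.41,769,959,3,697,900,3,3,3
6,Acenaphthene,6.56,942,960,3,919,935,3,3,3
7,o-hydroxybiphenyl,6.70,888,914,3,888,905,3,3,3
8,Fluorene,7.01,890,929,3,888,907,2,3,3
9,PCB 10,7.14,822,887,3,844,904,3,3,3
10,a-BHC,7.53,948,965,3,872,907,3,3,3
11,b-BHC,7.76,923,950,3,698,776,3,3,0
12,Lindane,7.83,920,938,3,848,889,3,3,2
13,Pyrimethanil,7.92,793,954,2,701,810,2,3,3
14,Phenanthrene,7.96,928,964,3,890,930,3,3,3
15,Anthracene,8.01,861,959,3,642,829,0,2,2
16,d-BHC,8.04,830,920,3,819,894,3,3,3
17,PCB 28,8.33,910,952,3,892,904,3,3,3
18,Parathion-methyl,8.39,761,842,3,488,736,1,0,0
19,Heptachlor,8.50,724,728,3,683,809,3,1,3
20,Fenchlorphos,8.51,664,728,2,629,703,3,3,2
21,PCB 52,8.63,944,962,3,857,877,3,3,0
22,Chlorpyrifos,8.80,900,906,3,474,467,3,3,0
23,Aldrin,8.83,919,921,3,745,739,3,3,3
24,Heptachlor epoxide,9.19,887,890,3,741,792,3,3,3
25,Fluoranthene,9.26,875,938,3,871,924,3,3,3
26,Pyrene,9.52,857,925,3,825,911,3,3,3
27,a-endosulfan,9.53,926,929,3,775,831,3,0,1
28,"4,4'-DDE",9.69,948,975,3,858,914,3,3,3
29,Dieldrin,9.77,930,931,3,810,830,3,2,3
30,Endrin,9.98,932,940,3,642,661,3,0,2
31,"p,p-DDD",10.10,845,937,3,829,909,3,3,3
32,PCB 153,10.21,912,954,3,881,915,3,3,3
33,Endrin aldehyde,10.23,924,926,3,760,783,2,2,2
34,"4,4-DDT",10.43,901,941,3,727,818,3,2,1
35,Endosulfan sulfate,10.45,864,869,3,749,772,2,1,0
36,PCB 137,10.48,853,902,3,801,910,3,3,3
37,Methoxychlor,10.99,732,805,3,673,818,3,3,3
38,Benz[a]anthracene,11.05,832,898,3,894,933,3,3,3
39,Chrysene,11.10,881,921,1,903,933,3,3,3
40,PCB 180,11.18,944,962,2,747,854,3,1,1
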