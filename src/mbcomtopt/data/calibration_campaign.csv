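run_id,phase,methanol_rate_ml_per_l_h,temperature_c,dmso_pct,observed_activity,predicted_activity,is_outlier
1,doe,1,20,4,126.1,122.2,false
2,doe,3,20,4,163.9,139.3,false
3,doe,1,30,4,47.4,97.0,false
4,doe,3,30,4,188.0,187.1,false
5,doe,1,20,6,138.0,143.8,false
6,doe,3,20,6,130.6,139.4,false
7,doe,1,30,6,151.4,97.5,false
8,doe,3,30,6,153.9,358.1,true
9,doe,1,25,5,105.3,116.5,false
10,doe,3,25,5,137.9,134.2,false
11,doe,2,20,5,115.2,136.8,false
12,doe,2,30,5,101.1,105.5,false
13,doe,2,25,4,183.9,197.2,false
14,doe,2,25,6,222.6,218.5,false
15,doe,2,25,5,252.5,243.3,false
16,doe,2,25,5,243.8,243.3,false
17,doe,2,25,5,230.3,243.3,false
18,iteration_1,1,22.5,6,364.3,343.1,false
19,iteration_1,1,22.5,6,364.6,343.1,false
20,iteration_1,1,22.5,6,357.6,343.1,false
21,iteration_2,2.9,30,6,390.6,383.1,false
22,iteration_2,2.9,30,6,391.5,383.1,false
23,iteration_3,3,30,6,377.1,358.1,false
24,iteration_3,3,30,6,377.4,358.1,false
25,iteration_4,2.5,30,6,263.0,258.9,false
26,iteration_4,2.5,30,6,283.7,258.9,false
27,final_validation,2.9,30,6,,384.8,false
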