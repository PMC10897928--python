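position,delta_c_ppm,carbon_type,delta_h_ppm,multiplicity_j_hz
2,87.1,CH,5.48,s
3,87.8,C,,
4,133.3,C,,
5,126.8,CH,7.78,d (8.2)
6,127.5,CH,7.37,t (7.6)
7,132.8,CH,7.55,m
8,118.4,CH,7.52,m
9,142.2,C,,
11,172.5,C,,
12,56.9,CH,5.93,t (9.8)
13a,32.6,CH2,2.77,dd (13.1 9.4)
13b,32.6,CH2,3.54,dd (13.1 10.2)
14,179.2,C,,
15,61.6,CH,3.83,q (7.0)
18,163.1,C,,
19,121.8,C,,
20,127.5,CH,8.23,d (8.0)
21,129.2,CH,7.60,t (7.7)
22,136.5,CH,7.89,t (7.7)
23,128.5,CH,7.76,d (8.5)
24,147.7,C,,
26,154.8,C,,
27,81.0,CH,5.64,d (9.7)
28,33.5,CH,2.49,m
29,19.1,CH3,0.97,d (6.5)
30,19.4,CH3,1.17,d (6.7)
32,171.8,C,,
33,20.7,CH3,2.22,s
34,17.9,CH3,1.50,d (7.0)
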