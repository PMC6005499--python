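sr,compound,fit_value,n_matched,activity_class
1,Cichoric acid,3.63,5,active
2,Amentoflavone,3.55,5,active
3,16,3.53,5,active
4,11,3.48,5,inactive
5,3,3.20,5,active
6,4,3.21,5,active
7,5,3.19,5,active
8,Chlorogenic acid,3.00,5,active
9,8,2.94,5,active
10,2,2.82,5,less_active
11,9,2.66,5,inactive
12,6,2.24,5,less_active
13,7,2.13,5,less_active
14,10,1.96,5,inactive
15,1,2.95,4,less_active
16,12,3.70,4,inactive
17,13,3.01,4,less_active
18,14,3.06,4,active
19,15,3.06,3,active
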