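run,soybean,glycerol,maltose,mgso4,nacl,point_type,split,observed,predicted_rsm,predicted_ann
1,0.375,0.375,0.375,0.0125,0.225,factorial,train,3.2,2.8171,3.2
2,0.375,0.375,0.375,0.0375,0.075,factorial,validation,2.21,2.02169,2.4
3,0.375,0.375,1.125,0.0125,0.075,factorial,train,1.622,1.76842,0.911
4,0.375,0.375,1.125,0.0375,0.225,factorial,train,3.08,2.71407,3.08
5,0.375,1.125,0.375,0.0125,0.075,factorial,test,2.822,2.93558,2.822
6,0.375,1.125,0.375,0.0375,0.225,factorial,train,3.08,2.08124,3.08
7,0.375,1.125,1.125,0.0125,0.225,factorial,train,2.822,1.6796,2.822
8,0.375,1.125,1.125,0.0375,0.075,factorial,validation,4.752,4.88255,5.8
9,1.125,0.375,0.375,0.0125,0.075,factorial,train,3.08,3.7313,3.522
10,1.125,0.375,0.375,0.0375,0.225,factorial,train,3.78,3.31896,4.77
11,1.125,0.375,1.125,0.0125,0.225,factorial,test,3.08,1.95369,3.08
12,1.125,0.375,1.125,0.0375,0.075,factorial,train,4.708,4.77628,4.708
13,1.125,1.125,0.375,0.0125,0.225,factorial,train,4.8,4.64085,4.8
14,1.125,1.125,0.375,0.0375,0.075,factorial,train,2.048,2.08344,1.94
15,1.125,1.125,1.125,0.0125,0.075,factorial,train,2.268,2.63817,2.1804
16,1.125,1.125,1.125,0.0375,0.225,factorial,test,4.708,4.56582,5.8564
17,0.0005,0.75,0.75,0.025,0.15,star,validation,1.222,1.85549,0.8492
18,1.5,0.75,0.75,0.025,0.15,star,train,2.926,2.93633,2.926
19,0.75,0.0005,0.75,0.025,0.15,star,train,2.756,3.41425,2.73
20,0.75,1.5,0.75,0.025,0.15,star,test,4.25,4.13571,4.25
21,0.75,0.75,0.0005,0.025,0.15,star,train,2.804,2.32791,2.804
22,0.75,0.75,1.5,0.025,0.15,star,train,4.365,4.18516,4.365
23,0.75,0.75,0.75,0.0005,0.15,star,train,2.282,2.829,2.282
24,0.75,0.75,0.75,0.5,0.15,star,train,2.4178,2.92038,2.4178
25,0.75,0.75,0.75,0.025,0.0005,star,validation,2.0282,2.74408,3.1949
26,0.75,0.75,0.75,0.025,0.3,star,train,2.4178,3.69553,2.4178
27,0.75,0.75,0.75,0.025,0.15,center,train,3.08,3.12288,3.181333
28,0.75,0.75,0.75,0.025,0.15,center,test,3.282,3.12288,3.181333
29,0.75,0.75,0.75,0.025,0.15,center,train,3.182,3.12288,3.181333
30,0.75,0.75,0.75,0.025,0.15,center,train,3.282,3.12288,3.181333
31,0.75,0.75,0.75,0.025,0.15,center,validation,3.024,3.12288,3.181333
32,0.75,0.75,0.75,0.025,0.15,center,test,3.282,3.12288,3.181333
33,0.75,0.75,0.75,0.025,0.15,center,train,3.282,3.12288,3.181333
34,0.75,0.75,0.75,0.025,0.15,center,validation,3.282,3.12288,3.181333
35,0.75,0.75,0.75,0.025,0.15,center,train,2.982,3.12288,2.4178
36,0.75,0.75,0.75,0.025,0.15,center,train,3.186,3.12288,3.181333
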