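subject_id,psi,tp,vlf,lf,hf
01,27.26,2145.09,604.52,750.00,803.20
02,57.65,1028.64,289.92,365.22,360.98
03,22.30,2049.12,524.03,568.10,932.14
04,25.36,1596.35,400.63,338.29,857.43
05,46.23,1728.75,582.13,552.13,606.88
06,30.14,2275.88,949.83,617.87,733.18
07,50.69,1067.97,404.82,283.35,404.79
08,26.79,2389.41,801.95,772.93,801.98
09,23.44,2502.94,754.11,952.96,795.85
10,36.24,1446.79,368.57,611.45,466.76
11,31.09,1787.25,718.50,521.25,546.75
12,79.06,610.50,236.25,119.00,255.00
13,70.80,1325.75,465.00,483.00,377.75
14,14.82,1416.00,595.00,331.25,489.25
15,43.47,1257.38,386.70,447.40,435.78
16,104.22,455.50,162.75,196.00,96.75
17,64.10,1681.50,598.88,724.25,358.38
18,51.25,1556.58,495.18,535.98,525.42
19,44.04,2294.51,816.94,988.38,489.19
20,94.19,786.73,271.78,328.06,186.88
21,74.93,968.00,350.63,301.00,316.38
22,42.81,1370.63,530.00,407.13,433.50
23,55.08,1198.38,477.38,320.13,400.88
24,50.94,1556.25,591.75,502.13,462.25
25,41.76,1012.88,415.63,225.13,372.13
26,36.49,1558.62,464.43,425.73,668.46
27,91.64,532.88,199.50,157.50,175.88
28,24.40,2049.65,577.37,645.62,826.64
29,28.20,1801.92,623.67,567.86,597.89
30,67.45,1503.63,531.94,603.63,368.06
31,49.49,1242.25,487.91,395.69,358.41
32,23.83,1822.74,462.33,453.19,907.20
33,25.34,1970.60,705.12,497.23,780.77
34,45.41,1449.10,519.39,433.61,496.11
35,37.07,1797.96,579.47,618.16,600.32
36,27.59,1819.95,537.24,601.09,681.63
37,23.99,2907.50,1035.00,1252.50,620.00
38,19.41,2161.50,815.00,791.88,554.63
39,84.16,1068.50,380.81,460.13,227.56
40,59.52,935.50,378.88,263.63,293.00
41,39.36,1592.55,548.11,461.37,583.06
42,36.86,1715.08,560.81,431.85,722.43
43,30.16,1690.68,463.38,439.46,787.83
44,58.49,1257.92,452.31,327.37,478.24
45,34.91,1749.37,548.38,539.62,661.38
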