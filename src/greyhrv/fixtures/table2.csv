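subject_id,psi,tp,vlf,lf,hf
01,38.09,1797.85,770.11,670.26,357.11
02,82.06,683.10,297.60,179.24,205.64
03,25.86,1685.74,524.09,371.14,790.71
04,42.72,1392.84,561.71,319.80,511.33
05,63.26,1186.25,466.13,428.13,290.50
06,44.21,1156.71,258.54,537.44,360.74
07,67.96,579.73,328.29,163.34,88.09
08,38.55,1325.08,447.01,572.10,305.98
09,32.88,1493.45,635.47,606.76,251.22
10,41.73,1165.58,425.87,280.80,458.92
11,43.30,2102.25,904.75,733.75,463.00
12,119.75,414.51,175.36,108.37,130.02
13,90.69,718.25,200.00,345.25,172.50
14,21.32,4598.75,2090.75,1937.00,571.00
15,54.48,833.96,345.06,242.86,246.05
16,150.57,307.00,100.75,104.25,102.00
17,91.71,1158.88,330.63,415.50,413.00
18,76.32,953.61,405.42,357.57,190.62
19,62.28,1603.33,445.56,571.13,586.61
20,123.84,517.31,185.50,177.13,154.66
21,105.22,566.25,187.68,226.44,152.14
22,56.01,2658.25,1145.38,1141.13,371.75
23,81.53,1257.88,540.06,421.06,296.51
24,67.00,1409.75,552.38,539.50,317.75
25,70.54,2506.25,1133.06,1022.69,350.51
26,38.51,1076.12,322.57,362.34,391.20
27,135.16,360.50,138.06,106.31,116.01
28,35.88,1415.10,615.21,438.54,361.35
29,37.85,1457.39,434.35,594.74,428.31
30,91.20,938.46,265.31,380.38,292.75
31,71.23,2665.93,1153.22,1098.44,414.25
32,36.31,1609.01,561.03,398.01,649.97
33,35.89,1500.08,495.02,573.60,431.46
34,69.68,1021.42,229.55,505.43,286.45
35,48.27,938.61,453.73,332.39,152.49
36,35.02,1852.71,953.15,631.80,267.76
37,32.84,2010.75,560.50,726.75,723.50
38,27.08,3304.75,1325.63,1331.88,647.25
39,121.14,733.08,215.69,259.88,257.50
40,85.39,2775.13,1372.75,1064.63,337.75
41,55.74,1326.50,569.28,473.37,283.85
42,49.28,2201.34,1160.47,690.25,350.62
43,37.41,1340.39,441.80,352.99,545.59
44,85.53,930.23,316.54,339.96,273.74
45,52.78,1218.26,422.38,471.98,323.90
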