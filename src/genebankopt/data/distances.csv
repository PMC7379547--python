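id,B1,B2,B3,B4,B5,B6,B7,B8,B9,B10,B11
B1,0,1274,1478,1028,1538,1045,495,1290,640,2402,1238
B2,1274,0,214,611,2572,2213,1761,740,1900,3687,39.7
B3,1478,214,0,682,2644,2285,1963,679,2103,3789,250
B4,1028,611,682,0,1962,1602,1498,290,1658,3107,631
B5,1538,2572,2644,1962,0,501,1374,2247,1950,1094,2593
B6,1045,2213,2285,1602,501,0,1027,2034,1603,1362,2379
B7,495,1761,1963,1498,1374,1027,0,1780,697,1912,1731
B8,1290,740,679,290,2247,2034,1780,0,1920,3369,728
B9,640,1900,2103,1658,1950,1603,697,1920,0,2578,1870
B10,2402,3687,3789,3107,1094,1362,1912,3369,2578,0,3657
B11,1238,39.7,250,631,2593,2379,1731,728,1870,3657,0
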