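class_id,center,width,amplitude
0,1655.0,28.0,0.8104
0,1545.0,26.0,0.5238
0,1455.0,18.0,0.2204
0,1400.0,16.0,0.1643
0,1240.0,24.0,0.2036
0,1080.0,22.0,0.1525
0,1025.0,16.0,0.22
0,1155.0,18.0,0.14
1,1655.0,28.0,0.8673
1,1545.0,26.0,0.4885
1,1455.0,18.0,0.2111
1,1400.0,16.0,0.1598
1,1240.0,24.0,0.1612
1,1080.0,22.0,0.1624
1,1085.0,18.0,0.24
1,1215.0,20.0,0.12
2,1655.0,28.0,0.7255
2,1545.0,26.0,0.468
2,1455.0,18.0,0.2225
2,1400.0,16.0,0.1693
2,1240.0,24.0,0.1704
2,1080.0,22.0,0.1631
2,1205.0,16.0,0.18
2,1338.0,14.0,0.12
3,1655.0,28.0,0.7583
3,1545.0,26.0,0.51
3,1455.0,18.0,0.2339
3,1400.0,16.0,0.1759
3,1240.0,24.0,0.1858
3,1080.0,22.0,0.146
3,1310.0,16.0,0.14
3,1175.0,14.0,0.1
4,1655.0,28.0,0.7919
4,1545.0,26.0,0.491
4,1455.0,18.0,0.2165
4,1400.0,16.0,0.1609
4,1240.0,24.0,0.1806
4,1080.0,22.0,0.1563
4,1265.0,18.0,0.14
4,1120.0,16.0,0.1
5,1655.0,28.0,0.8237
5,1545.0,26.0,0.5006
5,1455.0,18.0,0.2408
5,1400.0,16.0,0.1668
5,1240.0,24.0,0.185
5,1080.0,22.0,0.1669
5,1120.0,14.0,0.16
5,1575.0,14.0,0.1
6,1655.0,28.0,0.7154
6,1545.0,26.0,0.5039
6,1455.0,18.0,0.2311
6,1400.0,16.0,0.1589
6,1240.0,24.0,0.1871
6,1080.0,22.0,0.1503
6,1205.0,18.0,0.12
6,1032.0,14.0,0.12
7,1655.0,28.0,0.8754
7,1545.0,26.0,0.5021
7,1455.0,18.0,0.201
7,1400.0,16.0,0.1444
7,1240.0,24.0,0.2049
7,1080.0,22.0,0.1556
7,1050.0,20.0,0.18
7,1350.0,16.0,0.08
8,1655.0,28.0,0.7784
8,1545.0,26.0,0.4988
8,1455.0,18.0,0.2244
8,1400.0,16.0,0.1542
8,1240.0,24.0,0.1623
8,1080.0,22.0,0.1737
8,1305.0,14.0,0.18
8,1450.0,12.0,0.08
9,1655.0,28.0,0.762
9,1545.0,26.0,0.4594
9,1455.0,18.0,0.1871
9,1400.0,16.0,0.1536
9,1240.0,24.0,0.1786
9,1080.0,22.0,0.1682
9,1000.0,30.0,0.1
9,1700.0,24.0,0.08
10,1655.0,28.0,0.8298
10,1545.0,26.0,0.4838
10,1455.0,18.0,0.2325
10,1400.0,16.0,0.139
10,1240.0,24.0,0.1785
10,1080.0,22.0,0.1722
10,1745.0,18.0,0.28
10,1165.0,14.0,0.12
11,1655.0,28.0,0.8744
11,1545.0,26.0,0.5373
11,1455.0,18.0,0.2241
11,1400.0,16.0,0.1654
11,1240.0,24.0,0.1707
11,1080.0,22.0,0.1648
11,1090.0,16.0,0.2
11,1570.0,12.0,0.1
12,1655.0,28.0,0.762
12,1545.0,26.0,0.558
12,1455.0,18.0,0.2246
12,1400.0,16.0,0.1731
12,1240.0,24.0,0.1724
12,1080.0,22.0,0.1693
12,1585.0,14.0,0.16
12,1352.0,12.0,0.12
13,1655.0,28.0,0.8017
13,1545.0,26.0,0.4434
13,1455.0,18.0,0.2225
13,1400.0,16.0,0.155
13,1240.0,24.0,0.1756
13,1080.0,22.0,0.1641
13,1045.0,24.0,0.26
13,1380.0,14.0,0.1
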