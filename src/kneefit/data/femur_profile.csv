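y,z,is_outer
20.000000,45.000000,False
20.000000,43.807692,False
20.000000,42.615385,False
20.000000,41.423077,False
20.000000,40.230769,False
20.000000,39.038462,False
20.000000,37.846154,False
20.000000,36.653846,False
20.000000,35.461538,False
20.000000,34.269231,False
20.000000,33.076923,False
20.000000,31.884615,False
20.000000,30.692308,False
20.000000,29.500000,False
20.000000,28.307692,False
20.000000,27.115385,False
20.000000,25.923077,False
20.000000,24.730769,False
20.000000,23.538462,False
20.000000,22.346154,False
20.000000,21.153846,False
20.000000,19.961538,False
20.000000,18.769231,False
20.000000,17.576923,False
20.000000,16.384615,False
20.000000,15.192308,False
20.000000,14.000000,False
19.181818,13.181818,False
18.363636,12.363636,False
17.545455,11.545455,False
16.727273,10.727273,False
15.909091,9.909091,False
15.090909,9.090909,False
14.272727,8.272727,False
13.454545,7.454545,False
12.636364,6.636364,False
11.818182,5.818182,False
11.000000,5.000000,False
9.842105,5.000000,False
8.684211,5.000000,False
7.526316,5.000000,False
6.368421,5.000000,False
5.210526,5.000000,False
4.052632,5.000000,False
2.894737,5.000000,False
1.736842,5.000000,False
0.578947,5.000000,False
-0.578947,5.000000,False
-1.736842,5.000000,False
-2.894737,5.000000,False
-4.052632,5.000000,False
-5.210526,5.000000,False
-6.368421,5.000000,False
-7.526316,5.000000,False
-8.684211,5.000000,False
-9.842105,5.000000,False
-11.000000,5.000000,False
-11.818182,5.818182,False
-12.636364,6.636364,False
-13.454545,7.454545,False
-14.272727,8.272727,False
-15.090909,9.090909,False
-15.909091,9.909091,False
-16.727273,10.727273,False
-17.545455,11.545455,False
-18.363636,12.363636,False
-19.181818,13.181818,False
-20.000000,14.000000,False
-20.000000,15.166667,False
-20.000000,16.333333,False
-20.000000,17.500000,False
-20.000000,18.666667,False
-20.000000,19.833333,False
-20.000000,21.000000,False
-20.000000,22.166667,False
-20.000000,23.333333,False
-20.000000,24.500000,False
-20.000000,25.666667,False
-20.000000,26.833333,False
-20.000000,28.000000,False
-21.125000,28.000000,False
-22.250000,28.000000,False
-23.375000,28.000000,False
-24.500000,28.000000,False
-25.625000,28.000000,False
-26.750000,28.000000,False
-27.875000,28.000000,False
-29.000000,28.000000,True
-29.000000,26.833333,True
-29.000000,25.666667,True
-29.000000,24.500000,True
-29.000000,23.333333,True
-29.000000,22.166667,True
-29.000000,21.000000,True
-29.000000,19.833333,True
-29.000000,18.666667,True
-29.000000,17.500000,True
-29.000000,16.333333,True
-29.000000,15.166667,True
-29.000000,14.000000,True
-28.989159,13.558391,True
-28.956663,13.117846,True
-28.902589,12.679426,True
-28.827068,12.244187,True
-28.730281,11.813178,True
-28.612463,11.387438,True
-28.473897,10.967991,True
-28.314916,10.555849,True
-28.135904,10.152004,True
-27.937291,9.757429,True
-27.719557,9.373075,True
-27.483227,8.999868,True
-27.228868,8.638706,True
-26.957094,8.290460,True
-26.668560,7.955969,True
-26.363961,7.636039,True
-25.545779,6.817857,True
-24.727597,5.999675,True
-23.909416,5.181494,True
-23.091234,4.363312,True
-22.273052,3.545130,True
-21.454870,2.726948,True
-20.636688,1.908766,True
-19.818506,1.090584,True
-19.000325,0.272403,True
-18.182143,-0.545779,True
-17.363961,-1.363961,True
-17.044031,-1.668560,True
-16.709540,-1.957094,True
-16.361294,-2.228868,True
-16.000132,-2.483227,True
-15.626925,-2.719557,True
-15.242571,-2.937291,True
-14.847996,-3.135904,True
-14.444151,-3.314916,True
-14.032009,-3.473897,True
-13.612562,-3.612463,True
-13.186822,-3.730281,True
-12.755813,-3.827068,True
-12.320574,-3.902589,True
-11.882154,-3.956663,True
-11.441609,-3.989159,True
-11.000000,-4.000000,True
-9.842105,-4.000000,True
-8.684211,-4.000000,True
-7.526316,-4.000000,True
-6.368421,-4.000000,True
-5.210526,-4.000000,True
-4.052632,-4.000000,True
-2.894737,-4.000000,True
-1.736842,-4.000000,True
-0.578947,-4.000000,True
0.578947,-4.000000,True
1.736842,-4.000000,True
2.894737,-4.000000,True
4.052632,-4.000000,True
5.210526,-4.000000,True
6.368421,-4.000000,True
7.526316,-4.000000,True
8.684211,-4.000000,True
9.842105,-4.000000,True
11.000000,-4.000000,True
11.441609,-3.989159,True
11.882154,-3.956663,True
12.320574,-3.902589,True
12.755813,-3.827068,True
13.186822,-3.730281,True
13.612562,-3.612463,True
14.032009,-3.473897,True
14.444151,-3.314916,True
14.847996,-3.135904,True
15.242571,-2.937291,True
15.626925,-2.719557,True
16.000132,-2.483227,True
16.361294,-2.228868,True
16.709540,-1.957094,True
17.044031,-1.668560,True
17.363961,-1.363961,True
18.182143,-0.545779,True
19.000325,0.272403,True
19.818506,1.090584,True
20.636688,1.908766,True
21.454870,2.726948,True
22.273052,3.545130,True
23.091234,4.363312,True
23.909416,5.181494,True
24.727597,5.999675,True
25.545779,6.817857,True
26.363961,7.636039,True
26.668560,7.955969,True
26.957094,8.290460,True
27.228868,8.638706,True
27.483227,8.999868,True
27.719557,9.373075,True
27.937291,9.757429,True
28.135904,10.152004,True
28.314916,10.555849,True
28.473897,10.967991,True
28.612463,11.387438,True
28.730281,11.813178,True
28.827068,12.244187,True
28.902589,12.679426,True
28.956663,13.117846,True
28.989159,13.558391,True
29.000000,14.000000,True
29.000000,15.192308,True
29.000000,16.384615,True
29.000000,17.576923,True
29.000000,18.769231,True
29.000000,19.961538,True
29.000000,21.153846,True
29.000000,22.346154,True
29.000000,23.538462,True
29.000000,24.730769,True
29.000000,25.923077,True
29.000000,27.115385,True
29.000000,28.307692,True
29.000000,29.500000,True
29.000000,30.692308,True
29.000000,31.884615,True
29.000000,33.076923,True
29.000000,34.269231,True
29.000000,35.461538,True
29.000000,36.653846,True
29.000000,37.846154,True
29.000000,39.038462,True
29.000000,40.230769,True
29.000000,41.423077,True
29.000000,42.615385,True
29.000000,43.807692,True
29.000000,45.000000,True
27.875000,45.000000,False
26.750000,45.000000,False
25.625000,45.000000,False
24.500000,45.000000,False
23.375000,45.000000,False
22.250000,45.000000,False
21.125000,45.000000,False
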