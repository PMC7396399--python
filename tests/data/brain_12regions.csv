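frame_start_min,frame_end_min,CERCX,CAU,PUT,THA,LFC,LTC,HIP,LOC,LPC,ACC,PCC,AMG
0,0.3333333333,0.05292417953,0.03183495033,0.04341371936,0.04269202498,0.04195394016,0.04395883259,0.04384089255,0.04532151703,0.04447186099,0.04093182241,0.05367303059,0.03528839523
0.3333333333,0.6666666667,0.3493490047,0.2200552938,0.2985394359,0.2921957786,0.2878095369,0.2984834525,0.2983925408,0.3096108324,0.3017581201,0.2811797706,0.3577681516,0.237390935
0.6666666667,1,0.8955884853,0.5896134164,0.7958331075,0.7748497004,0.7653275918,0.7857650227,0.7863251596,0.8196435792,0.7937661937,0.7484288334,0.9264633929,0.6189771254
1,1.333333333,1.562037875,1.07637354,1.445089319,1.398417451,1.385912614,1.40798873,1.408587018,1.47686363,1.421015715,1.356217469,1.633978693,1.097510495
1.333333333,1.666666667,1.980777749,1.448474801,1.931118525,1.852407941,1.845153848,1.848752499,1.845540661,1.952547484,1.863344329,1.80638843,2.104431695,1.420312606
1.666666667,2,2.127166268,1.656411392,2.191723588,2.079643931,2.085172455,2.058191078,2.043118712,2.188265131,2.070916123,2.040697432,2.300912366,1.554909942
2,2.333333333,2.09386946,1.732509899,2.275228146,2.131915528,2.154641798,2.095430888,2.059550039,2.240421643,2.104186883,2.105925078,2.308485069,1.55490885
2.333333333,2.666666667,2.059584055,1.778811288,2.32245974,2.150440439,2.190621534,2.106855311,2.043132655,2.25912239,2.111641515,2.136202978,2.305391802,1.540364359
2.666666667,3,2.049126571,1.819481013,2.365537746,2.167313248,2.224002871,2.12269167,2.027504392,2.277673263,2.123911254,2.162709389,2.319207202,1.534497472
3,4,2.069662068,1.890027875,2.444789773,2.202472165,2.287694247,2.166033382,2.0066513,2.318784515,2.161332424,2.212028132,2.374089279,1.54406483
4,5,2.148427285,1.99325012,2.569170439,2.275356452,2.393543659,2.257887988,2.013371575,2.402685209,2.24632647,2.299281015,2.489266756,1.594978605
5,6,2.239484906,2.090628875,2.690894781,2.359612575,2.500559454,2.359702494,2.049723009,2.496933863,2.342774942,2.393908754,2.60801445,1.664101221
6,9,2.395312958,2.256005039,2.900016415,2.520172847,2.686934419,2.543885629,2.152053917,2.670259262,2.517992466,2.572532435,2.807809099,1.801091763
9,12,2.566981446,2.445200506,3.139066387,2.714277757,2.899837785,2.761232781,2.301015125,2.872940703,2.722946984,2.793872704,3.031579919,1.974560236
12,15,2.688776511,2.584177721,3.314236922,2.862261729,3.054770007,2.926948154,2.430966861,3.022578889,2.876806515,2.969494293,3.194265514,2.117875755
15,18,2.771649682,2.685704591,3.441443021,2.971654968,3.165608643,3.052177437,2.535425786,3.129850116,2.99045647,3.106654409,3.31057998,2.235459792
18,21,2.817550276,2.751626906,3.523006087,3.042626339,3.234344565,3.138116424,2.610219802,3.195891081,3.065152971,3.205034891,3.382982933,2.326943323
21,27,2.84414279,2.805660669,3.588547267,3.102820686,3.285826945,3.218840546,2.688724233,3.245544768,3.130079185,3.304365851,3.43878005,2.432617954
27,33,2.841857931,2.837417201,3.624883905,3.141028229,3.308531689,3.281253826,2.761334757,3.267607245,3.173138083,3.391350018,3.465055993,2.541906251
33,39,2.808993113,2.835207748,3.61826476,3.142704736,3.292879191,3.30413487,2.802973142,3.252379722,3.178731713,3.437324567,3.451255073,2.621523454
39,45,2.757472954,2.811155723,3.584113004,3.120307307,3.253026418,3.300193853,2.82211249,3.213423586,3.159527867,3.454650641,3.411866572,2.679028079
45,51,2.691187261,2.769150173,3.527393637,3.077841609,3.193493978,3.273651235,2.821354747,3.155075704,3.119710556,3.447294836,3.351689534,2.716802184
51,57,2.616356407,2.715285965,3.455920352,3.022080179,3.121475413,3.231354238,2.806307911,3.084467721,3.066055107,3.422116516,3.278211663,2.73930467
57,63,2.534941941,2.651924398,3.372651822,2.9553909,3.039583269,3.175889711,2.778601528,3.004057562,3.001030005,3.381693831,3.194138063,2.748103417
63,69,2.450868126,2.58283777,3.282445404,2.882135996,2.952272144,3.11174417,2.742183672,2.918339318,2.929017277,3.330582001,3.10420893,2.746369151
69,75,2.366750395,2.51106261,3.189121098,2.805509941,2.862949064,3.042324797,2.699631966,2.830589961,2.853264161,3.272310689,3.011912445,2.736449771
75,81,2.282595884,2.436975072,3.09311459,2.725869685,2.77190349,2.968207838,2.651303445,2.741054326,2.77420531,3.207542064,2.91758446,2.718878811
81,87,2.198409561,2.360853094,2.994752541,2.643566135,2.679352619,2.889897857,2.597721009,2.649955911,2.692222522,3.136902971,2.821479226,2.694189038
87,93,2.114340522,2.283049242,2.894465226,2.559047921,2.585623154,2.807981544,2.539503346,2.557635131,2.607790823,3.061095999,2.723973816,2.662980423
93,99,2.032964282,2.206022501,2.795422117,2.475235856,2.493618155,2.72548557,2.479520299,2.467053599,2.523829963,2.983282212,2.628169811,2.627615787
99,105,1.955837219,2.131687221,2.700015602,2.39412167,2.405447884,2.644589032,2.419454484,2.380224223,2.442372441,2.905789639,2.536211757,2.589765646
105,111,1.882377361,2.059763694,2.607849094,2.315355843,2.32065681,2.56512782,2.359135307,2.296664926,2.363130381,2.828559424,2.447652012,2.549571578
111,117,1.812081558,1.989960666,2.518526613,2.23866052,2.238816571,2.486947148,2.298577948,2.215962491,2.285846996,2.751563151,2.362065121,2.50719646
117,123,1.744178601,1.921760677,2.431354869,2.163465883,2.159224736,2.409584892,2.23748529,2.137412768,2.20996951,2.674456858,2.278713783,2.462547856
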