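sex,age,lambda0,mean_sbp,mean_tc,mean_smoker,mean_diabetes,target_risk10
female,40,0.0007651302268534506,118.0,5.1,0.25,0.03,0.00677206263915342
female,41,0.0007651302268534506,118.65,5.143999999999999,0.2465,0.0335,0.007370640803059825
female,42,0.0007651302268534506,119.3,5.186,0.243,0.037,0.008021912909241036
female,43,0.0007651302268534506,119.95,5.225999999999999,0.2395,0.0405,0.008730478125416608
female,44,0.0007651302268534506,120.6,5.263999999999999,0.236,0.044,0.00950132971190143
female,45,0.0007651302268534506,121.25,5.299999999999999,0.23249999999999998,0.0475,0.01033988742944203
female,46,0.0007651302268534506,121.9,5.334,0.229,0.051000000000000004,0.011252032356477426
female,47,0.0007651302268534506,122.55,5.366,0.2255,0.0545,0.012244144245512567
female,48,0.0007651302268534506,123.2,5.396,0.222,0.057999999999999996,0.0133231415448547
female,49,0.0007651302268534506,123.85,5.4239999999999995,0.2185,0.0615,0.014496524205645511
female,50,0.0014882364128514462,124.5,5.45,0.215,0.065,0.015772419384217473
female,51,0.0015305129982114878,125.15,5.474,0.2115,0.0685,0.017159630135528015
female,52,0.0015773568564774866,125.8,5.4959999999999996,0.208,0.07200000000000001,0.01866768717380285
female,53,0.0016291755606060616,126.45,5.516,0.20450000000000002,0.0755,0.020306903750452854
female,54,0.0016864146834973778,127.1,5.534,0.201,0.079,0.02208843366549318
female,55,0.0017495611901685105,127.75,5.55,0.1975,0.08249999999999999,0.024024332385577662
female,56,0.0018191471326617164,128.4,5.563999999999999,0.194,0.086,0.0261276211876037
female,57,0.0018957536746993706,129.05,5.576,0.1905,0.0895,0.028412354179611854
female,58,0.00198001547552536,129.7,5.585999999999999,0.187,0.093,0.030893687968078454
female,59,0.002072625464986521,130.35,5.594,0.1835,0.0965,0.0335879536400332
female,60,0.003041519621852019,131.0,5.6,0.18,0.1,0.03651273060673588
female,61,0.0032000210781771765,131.65,5.604,0.1765,0.1035,0.039686921709559786
female,62,0.0033743041367677055,132.3,5.606,0.173,0.107,0.04313082881452468
female,63,0.0035657587257413707,132.95,5.606,0.16949999999999998,0.1105,0.0468662279155051
female,64,0.0037759024556657623,133.6,5.603999999999999,0.16599999999999998,0.114,0.05091644252305538
female,65,0.004006391988112024,134.25,5.6,0.16249999999999998,0.11750000000000001,0.05530641383129986
female,66,0.004259035433656842,134.9,5.593999999999999,0.159,0.121,0.060062765824482445
female,67,0.0045358058724737,135.55,5.585999999999999,0.1555,0.1245,0.06521386310250499
female,68,0.004838856099159107,136.2,5.576,0.152,0.128,0.07078985876621391
female,69,0.005170534702683488,136.85,5.563999999999999,0.1485,0.1315,0.07682272920378408
female,70,0.006517610444207125,137.5,5.549999999999999,0.14500000000000002,0.135,0.08334629205559241
female,71,0.006964154913077803,138.15,5.533999999999999,0.14150000000000001,0.1385,0.09039620300403695
female,72,0.007452918365519805,138.8,5.515999999999999,0.138,0.14200000000000002,0.09800992633641115
female,73,0.007987626566331823,139.45,5.495999999999999,0.1345,0.14550000000000002,0.10622667346561943
female,74,0.008572345627981356,140.1,5.474,0.131,0.14900000000000002,0.11508730277160473
female,75,0.00921151256906956,140.75,5.449999999999999,0.1275,0.1525,0.12463417325762804
female,76,0.009909968675724048,141.4,5.4239999999999995,0.124,0.156,
female,77,0.01067299592264387,142.05,5.396,0.1205,0.1595,
female,78,0.011506356734308975,142.7,5.366,0.11699999999999999,0.163,
female,79,0.012416337392842095,143.35,5.334,0.11349999999999999,0.1665,
female,80,0.014483989629434096,144.0,5.299999999999999,0.10999999999999999,0.17,
female,81,0.015619777650630265,144.65,5.263999999999999,0.10649999999999998,0.17350000000000002,
female,82,0.01686003409818957,145.3,5.225999999999999,0.10300000000000001,0.177,
female,83,0.01821406281087701,145.95,5.185999999999999,0.0995,0.1805,
female,84,0.019692018062753402,146.6,5.144,0.096,0.184,
male,40,0.0016895812523326872,122.0,5.2,0.3,0.04,0.015416349154959819
male,41,0.0016895812523326872,122.5,5.229100000000001,0.296,0.043500000000000004,0.016557682594188883
male,42,0.0016895812523326872,123.0,5.2564,0.292,0.047,0.017782747833370416
male,43,0.0016895812523326872,123.5,5.2819,0.288,0.0505,0.019097569594842545
male,44,0.0016895812523326872,124.0,5.3056,0.284,0.054,0.020508587836786996
male,45,0.0016895812523326872,124.5,5.327500000000001,0.27999999999999997,0.0575,0.022022683524407505
male,46,0.0016895812523326872,125.0,5.3476,0.27599999999999997,0.061,0.023647205544208072
male,47,0.0016895812523326872,125.5,5.3659,0.27199999999999996,0.0645,0.025389998732622154
male,48,0.0016895812523326872,126.0,5.3824000000000005,0.268,0.068,0.027259432972034925
male,49,0.0016895812523326872,126.5,5.397100000000001,0.264,0.07150000000000001,0.029264433285566938
male,50,0.0029898277414459793,127.0,5.41,0.26,0.07500000000000001,0.03141451083633651
male,51,0.003059064980311467,127.5,5.4211,0.256,0.0785,0.03371979470674158
male,52,0.0031347392918236808,128.0,5.430400000000001,0.252,0.082,0.036191064297986686
male,53,0.0032173356748175196,128.5,5.4379,0.248,0.08549999999999999,0.03883978214894335
male,54,0.0033073772664301347,129.0,5.4436,0.244,0.089,0.04167812692575412
male,55,0.0034054281655382292,129.5,5.447500000000001,0.24,0.0925,0.044719026278561835
male,56,0.0035120964662107845,130.0,5.449599999999999,0.236,0.096,0.04797618919852498
male,57,0.0036280375167986544,130.5,5.4498999999999995,0.23199999999999998,0.0995,0.05146413743597367
male,58,0.0037539574214462664,131.0,5.4484,0.22799999999999998,0.10300000000000001,0.055198235458213674
male,59,0.0038906168020441533,131.5,5.4451,0.22399999999999998,0.10650000000000001,0.05919471833216383
male,60,0.005502535391783272,132.0,5.4399999999999995,0.21999999999999997,0.11000000000000001,0.06347071681173333
male,61,0.005735357966730139,132.5,5.4331000000000005,0.21599999999999997,0.11349999999999999,0.06804427879169994
male,62,0.005988134146976197,133.0,5.4244,0.212,0.11699999999999999,0.07293438615797998
male,63,0.00626234831719754,133.5,5.413900000000001,0.208,0.1205,0.07816096591785748
male,64,0.006559600374837583,134.0,5.4016,0.204,0.124,0.0837448943324468
male,65,0.0068816143363118224,134.5,5.3875,0.19999999999999998,0.1275,0.08970799259714501
male,66,0.007230247600820497,135.0,5.371600000000001,0.19599999999999998,0.131,0.0960730124242567
male,67,0.007607500921649407,135.5,5.353899999999999,0.192,0.1345,0.10286360967600927
male,68,0.00801552913865641,136.0,5.3344000000000005,0.188,0.138,0.11010430397721793
male,69,0.00845665272970139,136.5,5.3131,0.184,0.14150000000000001,0.11782042200715537
male,70,0.01051169160573344,137.0,5.29,0.18,0.145,0.12603802193313218
male,71,0.011099533745451005,137.5,5.2651,0.176,0.1485,0.1347837962086893
male,72,0.01173511628954874,138.0,5.2384,0.172,0.152,0.14408494972362706
male,73,0.012422000339382054,138.5,5.2099,0.16799999999999998,0.1555,0.15396905006992778
male,74,0.01316402335790444,139.0,5.179600000000001,0.16399999999999998,0.159,0.16446384648798007
male,75,0.013965320064601628,139.5,5.1475,0.15999999999999998,0.1625,0.17559705389530156
male,76,0.014830344957147468,140.0,5.1136,0.15599999999999997,0.166,
male,77,0.015763896585119192,140.5,5.0779000000000005,0.152,0.1695,
male,78,0.016771143710887122,141.0,5.0404,0.148,0.17300000000000001,
male,79,0.01785765350328064,141.5,5.0011,0.144,0.17650000000000002,
male,80,0.02068332145493105,142.0,4.960000000000001,0.13999999999999999,0.18000000000000002,
male,81,0.022019228125394683,142.5,4.9171,0.13599999999999998,0.18350000000000002,
male,82,0.023460343488345834,143.0,4.8724,0.13199999999999998,0.187,
male,83,0.02501459568099195,143.5,4.825900000000001,0.12799999999999997,0.1905,
male,84,0.026690529357021642,144.0,4.7776,0.124,0.194,
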