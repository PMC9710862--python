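sex,age,lambda0,mean_sbp,mean_bmi,mean_smoker,target_risk10
female,40,0.0007329746400472712,118.0,25.0,0.25,0.00677206263915342
female,41,0.0007329746400472712,118.65,25.078799999999998,0.2465,0.007370640803059825
female,42,0.0007329746400472712,119.3,25.1552,0.243,0.008021912909241036
female,43,0.0007329746400472712,119.95,25.2292,0.2395,0.008730478125416608
female,44,0.0007329746400472712,120.6,25.3008,0.236,0.00950132971190143
female,45,0.0007329746400472712,121.25,25.369999999999997,0.23249999999999998,0.01033988742944203
female,46,0.0007329746400472712,121.9,25.4368,0.229,0.011252032356477426
female,47,0.0007329746400472712,122.55,25.501199999999997,0.2255,0.012244144245512567
female,48,0.0007329746400472712,123.2,25.563200000000002,0.222,0.0133231415448547
female,49,0.0007329746400472712,123.85,25.622799999999998,0.2185,0.014496524205645511
female,50,0.001422281710085211,124.5,25.68,0.215,0.015772419384217473
female,51,0.0014709710896313084,125.15,25.7348,0.2115,0.017159630135528015
female,52,0.0015241618877013345,125.8,25.787200000000002,0.208,0.01866768717380285
female,53,0.0015822567821138377,126.45,25.8372,0.20450000000000002,0.020306903750452854
female,54,0.0016456946407415935,127.1,25.884800000000002,0.201,0.02208843366549318
female,55,0.0017149537596643483,127.75,25.93,0.1975,0.024024332385577662
female,56,0.0017905553904465007,128.4,25.9728,0.194,0.0261276211876037
female,57,0.001873067582307335,129.05,26.013199999999998,0.1905,0.028412354179611854
female,58,0.001963109367258252,129.7,26.0512,0.187,0.030893687968078454
female,59,0.002061355318763834,130.35,26.0868,0.1835,0.0335879536400332
female,60,0.0029624310999903283,131.0,26.12,0.18,0.03651273060673588
female,61,0.0031345056055162323,131.65,26.1508,0.1765,0.039686921709559786
female,62,0.003322190405141267,132.3,26.1792,0.173,0.04313082881452468
female,63,0.0035268730288858124,132.95,26.2052,0.16949999999999998,0.0468662279155051
female,64,0.0037500648257772313,133.6,26.228800000000003,0.16599999999999998,0.05091644252305538
female,65,0.0039934119867215245,134.25,26.25,0.16249999999999998,0.05530641383129986
female,66,0.00425870754839533,134.9,26.2688,0.159,0.060062765824482445
female,67,0.00454790446544844,135.55,26.2852,0.1555,0.06521386310250499
female,68,0.004863129846090798,136.2,26.299200000000003,0.152,0.07078985876621391
female,69,0.0052067004545818685,136.85,26.3108,0.1485,0.07682272920378408
female,70,0.006476530550653165,137.5,26.32,0.14500000000000002,0.08334629205559241
female,71,0.006945885289753783,138.15,26.3268,0.14150000000000001,0.09039620300403695
female,72,0.007457304872241221,138.8,26.3312,0.138,0.09800992633641115
female,73,0.008014516137102981,139.45,26.3332,0.1345,0.10622667346561943
female,74,0.008621577218293035,140.1,26.3328,0.131,0.11508730277160473
female,75,0.009282906973386126,140.75,26.330000000000002,0.1275,0.12463417325762804
female,76,0.010003317028669136,141.4,26.3248,0.124,
female,77,0.010788046673484842,142.05,26.3172,0.1205,
female,78,0.01164280085738498,142.7,26.307199999999998,0.11699999999999999,
female,79,0.012573791566229519,143.35,26.294800000000002,0.11349999999999999,
female,80,0.014579572734516141,144.0,26.28,0.10999999999999999,
female,81,0.01575099075673769,144.65,26.262800000000002,0.10649999999999998,
female,82,0.01702666820045081,145.3,26.243199999999998,0.10300000000000001,
female,83,0.018415832227848844,145.95,26.221200000000003,0.0995,
female,84,0.019928528998730516,146.6,26.1968,0.096,
male,40,0.0016348630077856385,122.0,25.5,0.3,0.015416349154959819
male,41,0.0016348630077856385,122.5,25.549,0.296,0.016557682594188883
male,42,0.0016348630077856385,123.0,25.596,0.292,0.017782747833370416
male,43,0.0016348630077856385,123.5,25.641,0.288,0.019097569594842545
male,44,0.0016348630077856385,124.0,25.684,0.284,0.020508587836786996
male,45,0.0016348630077856385,124.5,25.725,0.27999999999999997,0.022022683524407505
male,46,0.0016348630077856385,125.0,25.764,0.27599999999999997,0.023647205544208072
male,47,0.0016348630077856385,125.5,25.801000000000002,0.27199999999999996,0.025389998732622154
male,48,0.0016348630077856385,126.0,25.836,0.268,0.027259432972034925
male,49,0.0016348630077856385,126.5,25.869,0.264,0.029264433285566938
male,50,0.0029005227945226035,127.0,25.9,0.26,0.03141451083633651
male,51,0.0029796735897180495,127.5,25.929000000000002,0.256,0.03371979470674158
male,52,0.0030650024163816647,128.0,25.956000000000003,0.252,0.036191064297986686
male,53,0.003156975372915388,128.5,25.980999999999998,0.248,0.03883978214894335
male,54,0.0032560938121301707,129.0,26.003999999999998,0.244,0.04167812692575412
male,55,0.003362896992285737,129.5,26.025,0.24,0.044719026278561835
male,56,0.003477964926947956,130.0,26.044,0.236,0.04797618919852498
male,57,0.003601921448535623,130.5,26.061,0.23199999999999998,0.05146413743597367
male,58,0.0037354375015460745,131.0,26.075999999999997,0.22799999999999998,0.055198235458213674
male,59,0.003879234682636854,131.5,26.089,0.22399999999999998,0.05919471833216383
male,60,0.0054240665415635995,132.0,26.1,0.21999999999999997,0.06347071681173333
male,61,0.005676421423112136,132.5,26.109,0.21599999999999997,0.06804427879169994
male,62,0.005948135225630086,133.0,26.116,0.212,0.07293438615797998
male,63,0.006240660366174806,133.5,26.121,0.208,0.07816096591785748
male,64,0.006555558525997403,134.0,26.124,0.204,0.0837448943324468
male,65,0.00689450884296387,134.5,26.125,0.19999999999999998,0.08970799259714501
male,66,0.007259316717821914,135.0,26.124000000000002,0.19599999999999998,0.0960730124242567
male,67,0.007651923280262955,135.5,26.121000000000002,0.192,0.10286360967600927
male,68,0.008074415564191754,136.0,26.116,0.188,0.11010430397721793
male,69,0.008529037445295115,136.5,26.108999999999998,0.184,0.11782042200715537
male,70,0.01052300374208128,137.0,26.1,0.18,0.12603802193313218
male,71,0.011140760774165594,137.5,26.089000000000002,0.176,0.1347837962086893
male,72,0.011805358654125872,138.0,26.076,0.172,0.14408494972362706
male,73,0.012520301428666315,138.5,26.061,0.16799999999999998,0.15396905006992778
male,74,0.013289355990110555,139.0,26.044,0.16399999999999998,0.16446384648798007
male,75,0.014116571765806498,139.5,26.025,0.15999999999999998,0.17559705389530156
male,76,0.015006301883400136,140.0,26.004,0.15599999999999997,
male,77,0.015963225922644927,140.5,25.981,0.152,
male,78,0.016992374372736093,141.0,25.956,0.148,
male,79,0.018099154923068596,141.5,25.929,0.144,
male,80,0.020899189754442014,142.0,25.9,0.13999999999999999,
male,81,0.022275855907361704,142.5,25.869,0.13599999999999998,
male,82,0.02375616253928315,143.0,25.836000000000002,0.13199999999999998,
male,83,0.025347854678023318,143.5,25.801,0.12799999999999997,
male,84,0.027059257694128196,144.0,25.764,0.124,
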