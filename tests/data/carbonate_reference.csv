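mode,ta,ph,temp,sal,pco2
speciate,2000,7.70000000,8,30,844.364133
speciate,2000,7.70000000,8,35,821.961963
speciate,2000,7.70000000,8,38,813.912798
speciate,2000,7.70000000,13,30,865.752917
speciate,2000,7.70000000,13,35,840.708556
speciate,2000,7.70000000,13,38,831.239390
speciate,2000,7.70000000,20,30,889.826398
speciate,2000,7.70000000,20,35,860.568177
speciate,2000,7.70000000,20,38,848.787930
speciate,2000,7.90000000,8,30,514.822431
speciate,2000,7.90000000,8,35,498.736637
speciate,2000,7.90000000,8,38,492.406497
speciate,2000,7.90000000,13,30,524.452748
speciate,2000,7.90000000,13,35,506.403410
speciate,2000,7.90000000,13,38,498.991911
speciate,2000,7.90000000,20,30,533.305094
speciate,2000,7.90000000,20,35,512.196621
speciate,2000,7.90000000,20,38,503.079846
speciate,2000,8.10000000,8,30,308.408052
speciate,2000,8.10000000,8,35,296.668542
speciate,2000,8.10000000,8,38,291.662475
speciate,2000,8.10000000,13,30,311.242924
speciate,2000,8.10000000,13,35,298.097062
speciate,2000,8.10000000,13,38,292.306783
speciate,2000,8.10000000,20,30,311.718582
speciate,2000,8.10000000,20,35,296.474008
speciate,2000,8.10000000,20,38,289.508430
speciate,2000,8.30000000,8,30,180.189812
speciate,2000,8.30000000,8,35,171.630410
speciate,2000,8.30000000,8,38,167.745451
speciate,2000,8.30000000,13,30,179.496374
speciate,2000,8.30000000,13,35,170.012354
speciate,2000,8.30000000,13,38,165.612268
speciate,2000,8.30000000,20,30,176.105439
speciate,2000,8.30000000,20,35,165.337921
speciate,2000,8.30000000,20,38,160.224927
speciate,2150,7.70000000,8,30,908.491892
speciate,2150,7.70000000,8,35,884.575437
speciate,2150,7.70000000,8,38,876.029284
speciate,2150,7.70000000,13,30,931.634499
speciate,2150,7.70000000,13,35,904.905581
speciate,2150,7.70000000,13,38,894.850597
speciate,2150,7.70000000,20,30,957.756298
speciate,2150,7.70000000,20,35,926.540423
speciate,2150,7.70000000,20,38,914.028043
speciate,2150,7.90000000,8,30,554.183781
speciate,2150,7.90000000,8,35,537.041612
speciate,2150,7.90000000,8,38,530.332710
speciate,2150,7.90000000,13,30,564.667173
speciate,2150,7.90000000,13,35,545.436471
speciate,2150,7.90000000,13,38,537.579018
speciate,2150,7.90000000,20,30,574.390441
speciate,2150,7.90000000,20,35,551.903707
speciate,2150,7.90000000,20,38,542.233175
speciate,2150,8.10000000,8,30,332.217032
speciate,2150,8.10000000,8,35,319.725995
speciate,2150,8.10000000,8,38,314.426315
speciate,2150,8.10000000,13,30,335.370880
speciate,2150,8.10000000,13,35,321.383570
speciate,2150,8.10000000,13,38,315.250345
speciate,2150,8.10000000,20,30,336.044570
speciate,2150,8.10000000,20,35,319.821921
speciate,2150,8.10000000,20,38,312.437678
speciate,2150,8.30000000,8,30,194.288810
speciate,2150,8.30000000,8,35,185.190451
speciate,2150,8.30000000,8,38,181.078807
speciate,2150,8.30000000,13,30,193.621111
speciate,2150,8.30000000,13,35,183.537378
speciate,2150,8.30000000,13,38,178.876984
speciate,2150,8.30000000,20,30,190.088707
speciate,2150,8.30000000,20,35,178.634796
speciate,2150,8.30000000,20,38,173.213380
speciate,2300,7.70000000,8,30,972.619651
speciate,2300,7.70000000,8,35,947.188910
speciate,2300,7.70000000,8,38,938.145770
speciate,2300,7.70000000,13,30,997.516081
speciate,2300,7.70000000,13,35,969.102606
speciate,2300,7.70000000,13,38,958.461804
speciate,2300,7.70000000,20,30,1025.686198
speciate,2300,7.70000000,20,35,992.512669
speciate,2300,7.70000000,20,38,979.268156
speciate,2300,7.90000000,8,30,593.545132
speciate,2300,7.90000000,8,35,575.346586
speciate,2300,7.90000000,8,38,568.258922
speciate,2300,7.90000000,13,30,604.881597
speciate,2300,7.90000000,13,35,584.469532
speciate,2300,7.90000000,13,38,576.166125
speciate,2300,7.90000000,20,30,615.475788
speciate,2300,7.90000000,20,35,591.610794
speciate,2300,7.90000000,20,38,581.386504
speciate,2300,8.10000000,8,30,356.026012
speciate,2300,8.10000000,8,35,342.783448
speciate,2300,8.10000000,8,38,337.190155
speciate,2300,8.10000000,13,30,359.498836
speciate,2300,8.10000000,13,35,344.670078
speciate,2300,8.10000000,13,38,338.193907
speciate,2300,8.10000000,20,30,360.370558
speciate,2300,8.10000000,20,35,343.169834
speciate,2300,8.10000000,20,38,335.366926
speciate,2300,8.30000000,8,30,208.387808
speciate,2300,8.30000000,8,35,198.750492
speciate,2300,8.30000000,8,38,194.412164
speciate,2300,8.30000000,13,30,207.745847
speciate,2300,8.30000000,13,35,197.062401
speciate,2300,8.30000000,13,38,192.141700
speciate,2300,8.30000000,20,30,204.071976
speciate,2300,8.30000000,20,35,191.931670
speciate,2300,8.30000000,20,38,186.201832
speciate,2450,7.70000000,8,30,1036.747410
speciate,2450,7.70000000,8,35,1009.802383
speciate,2450,7.70000000,8,38,1000.262256
speciate,2450,7.70000000,13,30,1063.397663
speciate,2450,7.70000000,13,35,1033.299631
speciate,2450,7.70000000,13,38,1022.073012
speciate,2450,7.70000000,20,30,1093.616098
speciate,2450,7.70000000,20,35,1058.484916
speciate,2450,7.70000000,20,38,1044.508268
speciate,2450,7.90000000,8,30,632.906482
speciate,2450,7.90000000,8,35,613.651561
speciate,2450,7.90000000,8,38,606.185135
speciate,2450,7.90000000,13,30,645.096021
speciate,2450,7.90000000,13,35,623.502592
speciate,2450,7.90000000,13,38,614.753232
speciate,2450,7.90000000,20,30,656.561134
speciate,2450,7.90000000,20,35,631.317880
speciate,2450,7.90000000,20,38,620.539834
speciate,2450,8.10000000,8,30,379.834993
speciate,2450,8.10000000,8,35,365.840901
speciate,2450,8.10000000,8,38,359.953995
speciate,2450,8.10000000,13,30,383.626792
speciate,2450,8.10000000,13,35,367.956585
speciate,2450,8.10000000,13,38,361.137470
speciate,2450,8.10000000,20,30,384.696546
speciate,2450,8.10000000,20,35,366.517747
speciate,2450,8.10000000,20,38,358.296174
speciate,2450,8.30000000,8,30,222.486806
speciate,2450,8.30000000,8,35,212.310532
speciate,2450,8.30000000,8,38,207.745520
speciate,2450,8.30000000,13,30,221.870583
speciate,2450,8.30000000,13,35,210.587425
speciate,2450,8.30000000,13,38,205.406416
speciate,2450,8.30000000,20,30,218.055244
speciate,2450,8.30000000,20,35,205.228545
speciate,2450,8.30000000,20,38,199.190285
speciate,2500,7.70000000,8,30,1058.123329
speciate,2500,7.70000000,8,35,1030.673541
speciate,2500,7.70000000,8,38,1020.967752
speciate,2500,7.70000000,13,30,1085.358191
speciate,2500,7.70000000,13,35,1054.698639
speciate,2500,7.70000000,13,38,1043.276747
speciate,2500,7.70000000,20,30,1116.259398
speciate,2500,7.70000000,20,35,1080.475664
speciate,2500,7.70000000,20,38,1066.254973
speciate,2500,7.90000000,8,30,646.026932
speciate,2500,7.90000000,8,35,626.419886
speciate,2500,7.90000000,8,38,618.827206
speciate,2500,7.90000000,13,30,658.500829
speciate,2500,7.90000000,13,35,636.513613
speciate,2500,7.90000000,13,38,627.615601
speciate,2500,7.90000000,20,30,670.256250
speciate,2500,7.90000000,20,35,644.553576
speciate,2500,7.90000000,20,38,633.590943
speciate,2500,8.10000000,8,30,387.771320
speciate,2500,8.10000000,8,35,373.526719
speciate,2500,8.10000000,8,38,367.541942
speciate,2500,8.10000000,13,30,391.669444
speciate,2500,8.10000000,13,35,375.718755
speciate,2500,8.10000000,13,38,368.785324
speciate,2500,8.10000000,20,30,392.805209
speciate,2500,8.10000000,20,35,374.300385
speciate,2500,8.10000000,20,38,365.939257
speciate,2500,8.30000000,8,30,227.186472
speciate,2500,8.30000000,8,35,216.830546
speciate,2500,8.30000000,8,38,212.189972
speciate,2500,8.30000000,13,30,226.578829
speciate,2500,8.30000000,13,35,215.095766
speciate,2500,8.30000000,13,38,209.827988
speciate,2500,8.30000000,20,30,222.716334
speciate,2500,8.30000000,20,35,209.660836
speciate,2500,8.30000000,20,38,203.519769
solve_ph,2300,8.04296981,10,35,400.000000
solve_ph,2300,8.04464667,13,35,400.000000
solve_ph,2300,7.81858505,10,35,712.000000
solve_ph,2300,7.82282252,13,35,712.000000
solve_ph,2300,7.68191796,10,35,1000.000000
solve_ph,2300,7.68735516,13,35,1000.000000
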