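185
frame=0 closed=T bead_spacing=1 knot=K11n34 plat_word=-1_-2_3_-2_4_-3_-5_4_1_-3_2_2_4 certified_min_crossings=11 alexander=trivial
C 5.82130157 0.01904992 -0.00000043
C 5.83020051 1.01901032 -0.00003086
C 5.82929047 2.01900911 -0.00129324
C 5.80136262 3.01818758 -0.03066017
C 5.50880756 3.92949154 -0.32037838
C 4.96814676 4.71447568 -0.62284458
C 4.31121979 5.41687802 -0.34884112
C 3.70148192 6.01764374 0.16816980
C 3.04176310 6.70859487 0.46373300
C 2.40990076 7.46262322 0.28431385
C 2.07974797 8.38836584 0.09992369
C 1.97348488 9.37982353 0.02429424
C 1.94880619 10.37932433 0.00456840
C 1.94423797 11.37930624 0.00065531
C 1.94280692 12.37930424 -0.00074416
C 1.93207656 13.37918681 -0.01168484
C 1.84585089 14.37214811 -0.09288212
C 1.57851888 15.31939928 -0.26965547
C 1.13312392 16.19379327 -0.46216123
C 0.60168830 17.03839526 -0.39717148
C 0.26782655 17.95350134 -0.17108038
C 0.08986623 18.93175571 -0.06455096
C 0.02379173 19.92853320 -0.01906679
C 0.00504363 20.92824962 -0.00438391
C 0.00111351 21.92823541 -0.00078427
C 0.00408527 22.92823077 -0.00010779
C 0.02881776 23.92792487 -0.00001103
C 0.11822675 24.92391987 -0.00000081
C 0.41685045 25.87829080 -0.00000431
C 1.37496466 26.16467557 -0.00095740
C 1.78377641 25.25218264 -0.01611015
C 2.01977209 24.28395650 -0.09883968
C 2.38351474 23.37370010 -0.29663900
C 2.90396901 22.55189820 -0.52852043
C 3.46530597 21.78402938 -0.21984860
C 3.40273136 21.02579542 0.42912419
C 2.82629102 20.22163521 0.57418583
C 2.35551290 19.36837521 0.34987499
C 1.96402531 18.45332934 0.25277441
C 1.55895734 17.54213694 0.32792994
C 1.07552629 16.67799286 0.46774913
C 0.53824023 15.84591035 0.33004510
C 0.20100551 14.92431966 0.13783861
C 0.05515364 13.93976714 0.04096974
C 0.01164635 12.94122025 0.00917018
C 0.00194757 11.94129593 0.00160062
C 0.00026233 10.94129830 0.00022260
C 0.00002879 9.94129835 0.00002504
C 0.00000298 8.94129835 0.00000272
C 0.00000584 7.94129835 0.00000621
C 0.00006951 6.94129835 0.00007337
C 0.00072756 5.94129880 0.00075328
C 0.00619652 4.94132864 0.00620879
C 0.03963047 3.94236896 0.03722061
C 0.16597045 2.95504732 0.13331529
C 0.46102755 2.01147269 0.28367564
C 0.88349597 1.11610662 0.42453032
C 1.35073807 0.23391178 0.36607462
C 1.41748940 -0.74142359 0.15568171
C 0.51458780 -0.46334819 -0.17210295
C 0.71044258 0.48335081 -0.42784090
C 1.34204757 1.25428759 -0.50988739
C 2.01156787 1.99562027 -0.46332091
C 2.71636262 2.70450764 -0.43606201
C 3.40152834 3.40083264 -0.22233453
C 4.06463695 4.08233992 0.08723740
C 4.70665648 4.78604693 0.39155199
C 5.26583239 5.61035527 0.30301912
C 5.71188879 6.50300267 0.23810138
C 6.10065052 7.42323783 0.28317419
C 6.52094284 8.31798612 0.43410422
C 7.06888046 9.15432544 0.41675759
C 7.48456230 10.03528085 0.19064662
C 7.86876886 10.92792320 -0.04509678
C 8.26894707 11.80612976 -0.30703312
C 8.77546130 12.62752732 -0.56923414
C 9.19551640 13.49726769 -0.31018703
C 9.50675586 14.43121761 -0.13449539
C 9.65660054 15.41563233 -0.04243982
C 9.70454695 16.41394631 -0.00972370
C 9.71542547 17.41385453 -0.00164913
C 9.71724648 18.41385184 -0.00021017
C 9.71747113 19.41385180 -0.00002028
C 9.71744656 20.41385180 -0.00000148
C 9.71707799 21.41385173 -0.00000007
C 9.71466583 22.41384882 0.00000014
C 9.70223281 23.41377153 0.00000282
C 9.65215142 24.41251666 0.00005429
C 9.48258938 25.39803567 0.00105649
C 8.89878015 26.20968539 0.02084325
C 7.95667244 25.89316555 0.13151510
C 7.38516897 25.08982718 0.29894044
C 6.83092700 24.27980715 0.49046954
C 6.32177301 23.44196207 0.29354868
C 5.99405012 22.51331213 0.11974708
C 5.83533182 21.53278544 0.00409276
C 5.69334623 20.54859557 -0.10178636
C 5.42202883 19.60153498 -0.27343456
C 4.98203174 18.75001261 -0.55858752
C 4.48829726 17.88070340 -0.53561416
C 4.15240403 16.99408256 -0.21768458
C 3.96587729 16.02326069 -0.06697737
C 3.90739302 15.02654575 -0.01095121
C 3.91263381 14.02695632 0.01721793
C 3.98498442 13.03117595 0.07367001
C 4.19760299 12.06235620 0.20087712
C 4.61587171 11.17350345 0.38793880
C 5.21648344 10.37492065 0.34881021
C 5.84415765 9.68080498 -0.00365048
C 6.42352199 8.96258386 -0.38900145
C 7.11050926 8.23712802 -0.43098157
C 7.50552662 7.34894211 -0.19627524
C 7.70874642 6.38027343 -0.05350721
C 7.76443155 5.38284401 -0.00841045
C 7.77317633 4.38291112 -0.00081243
C 7.77450978 3.38291229 -0.00005026
C 7.77794515 2.38291820 -0.00000201
C 7.79544043 1.38307125 -0.00000005
C 7.86347583 0.38538834 -0.00000000
C 8.08426411 -0.58993342 -0.00000000
C 9.01791281 -0.94812346 0.00000000
C 9.51500246 -0.08042428 0.00000000
C 9.66007095 0.90899734 0.00000000
C 9.70522094 1.90797755 0.00000000
C 9.71557122 2.90792399 0.00000009
C 9.71726368 3.90792256 0.00000126
C 9.71746161 4.90792254 0.00001396
C 9.71736625 5.90792253 0.00011851
C 9.71656963 6.90792199 0.00078671
C 9.71223621 7.90790705 0.00411807
C 9.69346884 8.90764747 0.01703582
C 9.62899615 9.90481893 0.05566693
C 9.45731882 10.88596783 0.14440096
C 9.12143252 11.81391877 0.30591703
C 8.55992351 12.62721754 0.45840557
C 7.98309698 13.37328615 0.12576045
C 7.37666736 14.09919062 -0.19874813
C 6.74002870 14.84534474 -0.39354351
C 6.24961755 15.69972566 -0.22170010
C 5.80997514 16.57432740 -0.01728303
C 5.35862465 17.44231433 0.18979531
C 4.84150336 18.27918078 0.36935061
C 4.23660334 19.04331405 0.14530527
C 3.62042257 19.78463654 -0.12070643
C 3.01815737 20.52804007 -0.41161504
C 2.53021425 21.33087067 -0.06901535
C 2.74031954 22.16850804 0.43518639
C 3.23336850 23.03374927 0.34430001
C 3.62875248 23.93690156 0.17700552
C 3.94406028 24.87943541 0.06650242
C 4.32596011 25.80152899 0.00408483
C 5.25140484 26.17251406 -0.07287050
C 5.97108314 25.49264758 -0.21374172
C 6.49278546 24.66619905 -0.42542433
C 7.04251403 23.83090892 -0.43485273
C 7.47745761 22.95722768 -0.21689594
C 7.69745089 21.99337352 -0.06660249
C 7.76143870 20.99692363 -0.01189244
C 7.77202656 19.99703984 -0.00092497
C 7.77014805 18.99704999 0.00317087
C 7.75410712 17.99726629 0.01640898
C 7.69175028 17.00031344 0.06327725
C 7.51687589 16.02445805 0.19414057
C 7.19833606 15.12977817 0.50731830
C 6.62459834 14.31075169 0.50277457
C 6.16750143 13.46175926 0.23768161
C 5.80174148 12.56632426 -0.01612108
C 5.44733873 11.66356276 -0.25988404
C 4.95129634 10.84569602 -0.55149326
C 4.39278149 10.03947827 -0.35636740
C 3.95800870 9.16346215 -0.14763701
C 3.69626941 8.19863101 -0.17199730
C 3.30970865 7.29807174 -0.37090373
C 2.70874116 6.51141149 -0.51233826
C 2.20943633 5.69293219 -0.22810891
C 2.02872127 4.74024624 0.01629150
C 2.22745628 3.77921740 0.20845800
C 2.79895984 3.03619550 0.55674253
C 3.43099201 2.27711185 0.40077020
C 3.84784837 1.44097943 0.04424061
C 3.91713398 0.44432054 0.00099068
C 4.04133156 -0.54793648 0.00000914
C 4.28802547 -1.51702993 0.00000003
C 5.21905661 -1.88196968 0.00000000
C 5.59313263 -0.95457164 -0.00000000
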