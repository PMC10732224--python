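200
frame=0 closed=T bead_spacing=1 knot=K11n42 plat_word=4_4_-1_4_-1_-2_3_-2_3_4_4_-2_-1_-2_-1_2 certified_min_crossings=11 alexander=trivial
C 7.00521561 0.15065550 -0.37602383
C 6.29705365 0.80313435 -0.64579780
C 5.71821506 1.50368190 -0.22845019
C 5.93217580 2.17791497 0.47839531
C 6.59181050 2.91992315 0.59800270
C 6.97796688 3.78639743 0.28160804
C 7.02556289 4.70788303 -0.10387724
C 6.73891437 5.59901895 -0.45560071
C 6.25084948 6.47124556 -0.48743460
C 5.87748319 7.38194176 -0.31071435
C 5.64834662 8.34553554 -0.17293386
C 5.44076218 9.32370493 -0.16327238
C 5.14219430 10.27259103 -0.26560702
C 4.70872726 11.16341745 -0.40174895
C 4.19114131 12.01082232 -0.52011185
C 3.62435839 12.67631534 -0.03444101
C 3.21421482 13.40856980 0.50923689
C 2.63726711 14.22224291 0.43805112
C 2.27607802 15.13541560 0.24921769
C 2.04202744 16.09906059 0.12034309
C 1.93335084 17.08945010 0.03479761
C 1.94239198 18.08517313 -0.05714742
C 2.07818216 19.06492492 -0.20427823
C 2.33466622 20.01017152 -0.40608204
C 2.75801811 20.91351577 -0.47494679
C 3.07245412 21.83361398 -0.24138894
C 3.17305202 22.79545485 0.01305596
C 2.96701239 23.73230859 0.29563822
C 2.49362527 24.59586858 0.46932984
C 1.90527993 25.40065717 0.54784790
C 1.29216016 26.18467773 0.64478040
C 0.73939080 26.99529773 0.45154152
C 0.40785842 27.91588308 0.24512232
C 0.30371711 28.90300065 0.12365835
C 0.77278552 29.78152734 0.03329417
C 1.68543103 29.48390524 -0.24688300
C 2.34250903 28.78459910 -0.52834248
C 2.92438785 27.97248579 -0.48487984
C 3.23809402 27.04452642 -0.28368378
C 3.17286837 26.04700503 -0.31007870
C 2.77387812 25.13784776 -0.42940946
C 2.20887060 24.31594212 -0.50178084
C 1.60859749 23.51614761 -0.50275087
C 1.03849173 22.69535984 -0.46687807
C 0.60270255 21.81219596 -0.29335763
C 0.30858032 20.86618407 -0.15714591
C 0.13966325 19.88393252 -0.07560511
C 0.05634933 18.88830369 -0.03339104
C 0.02075934 17.88914213 -0.01315409
C 0.00714194 16.88926980 -0.00479403
C 0.00234089 15.88928627 -0.00164957
C 0.00108703 14.88928809 -0.00021274
C 0.00344147 13.88929482 0.00260188
C 0.01715287 12.88944503 0.01320371
C 0.06367621 11.89101117 0.04427467
C 0.17852174 10.89972227 0.10874801
C 0.38659181 9.92736506 0.21471169
C 0.68163325 8.98213985 0.35435359
C 1.05082766 8.06039824 0.47304604
C 1.40205321 7.15140138 0.24862386
C 1.43124970 6.22754593 -0.13300248
C 1.18349067 5.30510195 -0.42916557
C 0.77726120 4.39265352 -0.47831304
C 0.48636618 3.45297724 -0.29834475
C 0.27861206 2.48404114 -0.16417676
C 0.18335948 1.49236237 -0.07757322
C 0.26012217 0.49638082 -0.03144046
C 0.88553640 -0.28360206 -0.00944627
C 1.54408265 0.46874008 0.00782073
C 1.64738273 1.46195712 0.06119668
C 1.57488201 2.45216197 0.18051982
C 1.34302802 3.40962484 0.35230044
C 1.01824174 4.33617264 0.54209780
C 0.60482719 5.24148900 0.44467765
C 0.40701721 6.15379215 0.08610523
C 0.53115081 7.05465063 -0.32988137
C 1.01581169 7.89753476 -0.56365515
C 1.60643734 8.70302623 -0.51523167
C 2.26427204 9.45294547 -0.44541303
C 2.96960308 10.15661434 -0.35963285
C 3.54587504 10.87328930 0.03316180
C 4.09965565 11.59900045 0.44141461
C 4.58312806 12.46844102 0.33979019
C 4.69706217 13.41752125 0.04607990
C 4.70572744 14.36640616 -0.26942342
C 4.52807079 15.31237023 -0.54069837
C 4.24819898 16.26199258 -0.39966944
C 3.96955655 17.20470028 -0.21620120
C 3.69430911 18.14671454 -0.02424294
C 3.39130366 19.07954166 0.17074748
C 3.02196130 19.98325950 0.38726606
C 2.50635760 20.82623590 0.54070532
C 1.96035453 21.66343960 0.50955086
C 1.39958000 22.49132389 0.49773823
C 0.89252365 23.34153781 0.35621033
C 0.61717384 24.26981469 0.10624130
C 0.67897286 25.23214838 -0.15851284
C 1.03039176 26.14387681 -0.37124744
C 1.57351960 26.96269587 -0.18537784
C 2.12399017 27.72219258 0.16124428
C 2.71831069 28.48819945 0.40622713
C 3.33605844 29.26295049 0.27151061
C 4.14928314 29.82280221 0.11266593
C 4.99682507 29.29898807 0.02727603
C 5.29503882 28.34470196 0.00711258
C 5.43256497 27.35421990 0.00146803
C 5.45745927 26.35453117 -0.00018088
C 5.48108675 25.35482235 -0.00508103
C 5.50605121 24.35525007 -0.02031349
C 5.55918288 23.35746201 -0.06026372
C 5.66274708 22.36646780 -0.14514560
C 5.83725177 21.39251244 -0.28991803
C 6.09666950 20.44823608 -0.49251269
C 6.51710033 19.54101094 -0.50594667
C 6.74389977 18.66644740 -0.07734356
C 6.44009325 17.84604789 0.40705941
C 5.80197586 17.07842021 0.46667443
C 5.14628722 16.32360420 0.48470767
C 4.47485565 15.58263777 0.47252599
C 3.87269600 14.85626860 0.14117786
C 3.39505631 14.08266486 -0.27523249
C 2.86537152 13.25700644 -0.46945454
C 2.63505113 12.34101526 -0.14095389
C 2.54358694 11.40921879 0.21031472
C 2.58591610 10.47498241 0.56444836
C 2.88497558 9.52496401 0.47484665
C 3.17359188 8.58473568 0.29409456
C 3.38975976 7.61908881 0.14988090
C 3.52663067 6.63183420 0.06867327
C 3.60024809 5.63532576 0.02928545
C 3.63482528 4.63608188 0.01150638
C 3.65146758 3.63624711 0.00419419
C 3.66632560 2.63636082 0.00161549
C 3.69848817 1.63688013 -0.00036373
C 3.82264298 0.64462195 -0.00341147
C 4.35916812 -0.19828644 0.03716216
C 5.34332859 -0.12671677 0.19935328
C 6.07102633 0.54329543 0.34611721
C 6.66793796 1.32902965 0.18388827
C 6.62022771 2.19462538 -0.31457716
C 6.22004952 3.10964797 -0.36547967
C 6.03197295 4.05197155 -0.08861602
C 6.06829223 5.00640076 0.20760315
C 6.29431843 5.95567007 0.42623512
C 6.62757720 6.89812922 0.39960197
C 6.87771539 7.85836367 0.27558305
C 7.04628724 8.83725546 0.16002180
C 7.15412981 9.82846664 0.08340344
C 7.20946543 10.82569614 0.03369137
C 7.21490503 11.82491016 -0.00557377
C 7.16782278 12.82289680 -0.04807013
C 7.06063059 13.81543310 -0.10622086
C 6.88459671 14.79605363 -0.19221773
C 6.63207089 15.75682485 -0.30688847
C 6.29487488 16.69263706 -0.40962286
C 5.87411570 17.59922418 -0.44220349
C 5.71276556 18.48287821 -0.00274735
C 6.06432105 19.32047736 0.41538708
C 6.50738875 20.21645569 0.44561712
C 6.79576861 21.16356785 0.30484923
C 7.00435026 22.13394769 0.18296134
C 7.14325897 23.12051680 0.09702083
C 7.22980573 24.11547907 0.04642699
C 7.28036206 25.11385644 0.02022239
C 7.31310475 26.11324539 0.00798916
C 7.35245240 27.11245771 0.00284215
C 7.44944449 28.10774098 0.00090577
C 7.82780269 29.03340000 0.00023374
C 8.81316854 28.86294743 0.00000548
C 9.06955878 27.89637408 -0.00000081
C 9.07809187 26.89641049 0.00000067
C 9.15898563 25.89968776 -0.00000074
C 9.10851161 24.90096239 0.00000057
C 9.15010368 23.90182771 -0.00000030
C 9.12933020 22.90204350 0.00000015
C 9.13996083 21.90210001 -0.00000006
C 9.13572631 20.90210898 0.00000002
C 9.13701920 19.90210981 -0.00000000
C 9.13686574 18.90210982 -0.00000000
C 9.13674778 17.90210983 0.00000000
C 9.13685867 16.90210984 -0.00000000
C 9.13680015 15.90210984 0.00000000
C 9.13681709 14.90210984 0.00000000
C 9.13681781 13.90210984 0.00000000
C 9.13681815 12.90210984 0.00000000
C 9.13681814 11.90210984 -0.00000000
C 9.13681846 10.90210984 0.00000000
C 9.13681744 9.90210984 -0.00000002
C 9.13681903 8.90210984 0.00000013
C 9.13682195 7.90210984 -0.00000060
C 9.13677730 6.90210984 0.00000312
C 9.13693300 5.90210985 -0.00000732
C 9.13664025 4.90210990 0.00000836
C 9.13675344 3.90210990 -0.00001616
C 9.13420663 2.90211315 0.00004703
C 9.12437254 1.90216150 0.00000007
C 9.07681610 0.90329345 -0.00100062
C 8.96994633 -0.09096130 0.00502672
C 8.49688627 -0.97198983 0.00673567
C 7.56247202 -0.63984738 -0.12191661
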