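sex,age_lo,intake_mean,intake_sd
female,20,0.2807092974820154,0.09824825411870539
female,25,0.3070278217795561,0.10745973762284464
female,30,0.258649576763178,0.0905273518671123
female,35,0.3069189668282346,0.10742163838988211
female,40,0.26870988712062915,0.0940484604922202
female,45,0.27539958693835453,0.09638985542842408
female,50,0.2996621556292265,0.10488175447022927
female,55,0.2745519481821497,0.09609318186375237
female,60,0.28297562126038356,0.09904146744113423
female,65,0.2516535467945841,0.08807874137810444
female,70,0.2952107865204884,0.10332377528217093
female,75,0.2822885987931567,0.09880100957760485
female,80,0.26978390298994553,0.09442436604648093
female,85,0.2973057222057043,0.10405700277199649
female,90,0.2681916897574987,0.09386709141512453
male,20,0.27720987336883907,0.09702345567909366
male,25,0.2580425018348299,0.09031487564219046
male,30,0.27418677918682777,0.09596537271538971
male,35,0.262207314440569,0.09177256005419915
male,40,0.265738800426511,0.09300858014927885
male,45,0.29502188035780313,0.10325765812523109
male,50,0.2668245254791624,0.09338858391770684
male,55,0.2791114584658981,0.09768901046306432
male,60,0.3088442319880743,0.108095481195826
male,65,0.3076994316198272,0.10769480106693952
male,70,0.29348739644641203,0.10272058875624421
male,75,0.28247361133284604,0.09886576396649611
male,80,0.26661347224272225,0.09331471528495278
male,85,0.2596391205265076,0.09087369218427765
male,90,0.30819552479296797,0.10786843367753879
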