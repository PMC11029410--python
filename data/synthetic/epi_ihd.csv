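sex,age_lo,ihd_inc,ihd_prev,ihd_mort,ihd_yld_rate,other_yld_rate
female,20,0.00012113791079679323,0.0008334009843529738,6.66720787482379e-05,6.66720787482379e-05,0.06
female,25,0.00018071652714732125,0.001057680646851519,8.461445174812152e-05,8.461445174812152e-05,0.065
female,30,0.00026959737847033293,0.0014533085158853997,0.00011626468127083198,0.00011626468127083198,0.06999999999999999
female,35,0.0004021920276213836,0.0020842723668218184,0.00016674178934574549,0.00016674178934574549,0.075
female,40,0.0006,0.003052509390921601,0.0002442007512737281,0.0002442007512737281,0.08
female,45,0.0008950948185847622,0.004514184818078345,0.0003611347854462676,0.0003611347854462676,0.08499999999999999
female,50,0.0013353245570954806,0.0067044533973786204,0.0005363562717902897,0.0005363562717902897,0.09
female,55,0.001992070153641928,0.009974340501360996,0.0007979472401088797,0.0007979472401088797,0.095
female,60,0.0029718194546370686,0.014844879676116345,0.0011875903740893076,0.0011875903740893076,0.1
female,65,0.00443343365935839,0.022085405972469073,0.0017668324777975258,0.0017668324777975258,0.105
female,70,0.00661390582838496,0.03282451408402867,0.0026259611267222937,0.0026259611267222937,0.11
female,75,0.009866788062658232,0.04870234764447724,0.0038961878115581793,0.0038961878115581793,0.11499999999999999
female,80,0.01471951811826561,0.07206815499904538,0.005765452399923631,0.005765452399923631,0.12
female,85,0.02195894066620679,0.10620905913057835,0.008496724730446268,0.008496724730446268,0.125
female,90,0.032758890019886536,0.15554556900007802,0.012443645520006241,0.012443645520006241,0.13
male,20,0.00016959307511551052,0.0011665160865638052,9.332128692510441e-05,9.332128692510441e-05,0.06
male,25,0.00025300313800624973,0.0014804909933846917,0.00011843927947077533,0.00011843927947077533,0.065
male,30,0.0003774363298584661,0.002034227416671789,0.00016273819333374314,0.00016273819333374314,0.06999999999999999
male,35,0.000563068838669937,0.002917194815592373,0.00023337558524738982,0.00023337558524738982,0.075
male,40,0.0008399999999999999,0.0042718359025951886,0.0003417468722076151,0.0003417468722076151,0.08
male,45,0.0012531327460186669,0.006316172975256933,0.0005052938380205546,0.0005052938380205546,0.08499999999999999
male,50,0.0018694543799336726,0.009378061426999549,0.0007502449141599639,0.0007502449141599639,0.09
male,55,0.002788898215098699,0.013945902836270722,0.001115672226901658,0.001115672226901658,0.095
male,60,0.004160547236491896,0.020742386543847576,0.0016593909235078062,0.0016593909235078062,0.1
male,65,0.006206807123101745,0.03082953094521315,0.002466362475617052,0.002466362475617052,0.105
male,70,0.009259468159738944,0.0457538452367698,0.003660307618941584,0.003660307618941584,0.11
male,75,0.013813503287721525,0.06773686666304789,0.005418949333043831,0.005418949333043831,0.11499999999999999
male,80,0.020607325365571853,0.0999013530232142,0.007992108241857136,0.007992108241857136,0.12
male,85,0.030742516932689506,0.14648014445176646,0.011718411556141317,0.011718411556141317,0.125
male,90,0.04586244602784115,0.21284680378702148,0.01702774430296172,0.01702774430296172,0.13
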