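sex,age_lo,ihd_incident_min,ihd_incident_mode,ihd_incident_max,ihd_prevalent_min,ihd_prevalent_mode,ihd_prevalent_max,nonihd_percap
female,20,150.0,300.0,600.0,75.0,150.0,300.0,30.0
female,25,150.0,300.0,600.0,75.0,150.0,300.0,32.336524526538945
female,30,150.0,300.0,600.0,75.0,150.0,300.0,34.85502728184849
female,35,150.0,300.0,600.0,75.0,150.0,300.0,37.569681485755936
female,40,150.0,300.0,600.0,75.0,150.0,300.0,40.4957642272801
female,45,150.0,300.0,600.0,75.0,150.0,300.0,43.649742438546035
female,50,150.0,300.0,600.0,75.0,150.0,300.0,47.04936556470506
female,55,150.0,300.0,600.0,75.0,150.0,300.0,50.713765451372744
female,60,150.0,300.0,600.0,75.0,150.0,300.0,54.663564011715266
female,65,150.0,300.0,600.0,75.0,150.0,300.0,58.920989279095416
female,70,150.0,300.0,600.0,75.0,150.0,300.0,63.51000049838024
female,75,150.0,300.0,600.0,75.0,150.0,300.0,68.4564229598791
female,80,150.0,300.0,600.0,75.0,150.0,300.0,73.78809333470848
female,85,150.0,300.0,600.0,75.0,150.0,300.0,79.5350163294782
female,90,150.0,300.0,600.0,75.0,150.0,300.0,85.72953354189491
male,20,150.0,300.0,600.0,75.0,150.0,300.0,30.0
male,25,150.0,300.0,600.0,75.0,150.0,300.0,32.336524526538945
male,30,150.0,300.0,600.0,75.0,150.0,300.0,34.85502728184849
male,35,150.0,300.0,600.0,75.0,150.0,300.0,37.569681485755936
male,40,150.0,300.0,600.0,75.0,150.0,300.0,40.4957642272801
male,45,150.0,300.0,600.0,75.0,150.0,300.0,43.649742438546035
male,50,150.0,300.0,600.0,75.0,150.0,300.0,47.04936556470506
male,55,150.0,300.0,600.0,75.0,150.0,300.0,50.713765451372744
male,60,150.0,300.0,600.0,75.0,150.0,300.0,54.663564011715266
male,65,150.0,300.0,600.0,75.0,150.0,300.0,58.920989279095416
male,70,150.0,300.0,600.0,75.0,150.0,300.0,63.51000049838024
male,75,150.0,300.0,600.0,75.0,150.0,300.0,68.4564229598791
male,80,150.0,300.0,600.0,75.0,150.0,300.0,73.78809333470848
male,85,150.0,300.0,600.0,75.0,150.0,300.0,79.5350163294782
male,90,150.0,300.0,600.0,75.0,150.0,300.0,85.72953354189491
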