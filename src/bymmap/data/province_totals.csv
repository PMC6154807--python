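area_id,population,obs_overall,exp_overall,obs_male,exp_male,obs_female,exp_female
Chiang Mai,1294412,4141,3356,2390,1965,1751,1391
Chiang Rai,935620,2181,2265,1208,1350,973,915
Lampang,644750,1635,1811,1026,1063,609,748
Lamphun,343326,735,963,450,567,285,396
Phrae,390093,913,1062,580,604,333,458
Phayao,410391,863,1011,494,599,369,412
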