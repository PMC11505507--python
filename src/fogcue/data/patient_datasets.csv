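subject,updrs,hoehn_yahr,gender,medicated,age,fog_pct,other_pct,n_fog_episodes,n_samples
1,71,3,M,yes,90,4.7,95.3,,54030
2,49,3,F,yes,75,1.5,98.5,8,97227
3,44,2,M,yes,70,1.9,98.1,10,99175
4,57,3,M,yes,81,8.6,91.4,16,58620
5,44,2,M,yes,56,7.6,92.4,86,92987
6,29,3,F,yes,59,3.0,97.0,6,25313
7,62,3,M,yes,73,6.2,93.8,7,9480
8,49,3,F,yes,51,4.8,95.2,4,12309
9,47,3,M,yes,52,15.4,84.6,13,14055
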