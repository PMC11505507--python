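patient,condition,total,fog
7,without,9480,586
7,with,16991,720
8,without,12309,562
8,with,8412,217
9,without,14055,2168
9,with,9077,593
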