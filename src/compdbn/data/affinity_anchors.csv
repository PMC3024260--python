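pH,calcium_mM,affinity
5.5,2.5,203.82464096749797
6.0,2.5,90.60846560846554
6.5,2.5,30.0
7.0,2.5,5.559334845049121
7.4,2.5,1.0
5.5,2.0,681.4134542705966
6.0,2.0,302.72486772486747
6.5,2.0,100.0
7.0,2.0,18.250188964474646
7.4,2.0,3.0
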