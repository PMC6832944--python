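class,A,B,C,D,E,F,G,H,I,J
% of total time,20.1,7.6,7.5,3.4,17.0,3.8,24.3,10.1,4.7,1.7
seated,25.5,10.2,8.7,4.6,22.5,4.8,1.9,16.0,5.2,0.5
standing,14.3,0.0,13.0,0.2,2.4,2.2,53.4,12.3,1.3,0.9
household,4.2,0.2,2.1,0.1,1.2,0.4,16.9,66.4,2.1,6.4
indoor_walking,0.0,0.0,0.0,0.0,0.2,0.2,62.1,25.7,7.8,4.0
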