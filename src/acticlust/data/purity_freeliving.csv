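class,A,B,C,D,E,F,G,H,I,J
% of total time,20.2,2.2,6.2,2.4,15.9,8.6,27.2,6.8,7.4,3.1
sedentary,19.7,3.6,7.5,3.9,23.7,12.4,14.8,2.1,11.4,0.8
standing,26.2,0.2,5.5,0.3,7.7,4.0,38.1,10.4,1.9,5.8
stepping,14.4,0.1,3.3,0.1,1.6,2.3,52.6,17.3,1.5,6.8
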