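class,A,B,C,D,E,F,G,H,I,J
% of total time,6.5,13.1,19.9,0.2,5.5,12.3,5.7,2.5,14.7,19.7
lying,6.7,24.0,29.3,0.5,11.4,15.6,5.0,3.5,3.1,0.9
seated,31.1,15.1,38.9,0.0,0.5,8.7,0.3,3.7,1.5,0.3
treadmill_walking,0.0,0.0,4.6,0.0,0.0,18.2,0.2,12.6,57.7,6.7
running,0.0,0.0,3.9,0.0,0.0,0.3,0.1,4.5,3.9,87.3
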