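class,A,B,C,D,E,F,G,H,I,J
% of total time,9.1,3.9,6.9,4.4,12.2,15.7,11.6,7.2,24.2,4.8
lying,12.2,24.6,22.2,16.0,21.2,1.4,2.0,0.2,0.1,0.0
seated,23.3,0.2,13.5,8.1,37.0,12.2,2.6,2.4,0.7,0.1
standing,0.4,0.0,0.6,0.3,0.0,65.9,29.3,2.4,1.1,0.0
household,8.1,0.1,0.8,0.0,1.4,16.9,9.8,44.6,15.6,2.8
indoor_walking,2.6,0.1,0.3,0.0,0.6,0.0,55.4,30.6,4.2,6.3
treadmill_walking,0.0,0.0,0.6,0.0,0.1,16.0,1.8,3.5,77.8,0.3
brisk_walking,0.0,0.0,0.0,0.0,0.0,1.4,2.5,9.5,84.5,2.2
stairs,1.4,0.0,0.1,0.0,0.1,17.1,1.8,4.0,75.4,0.2
running,0.0,0.0,0.0,0.0,0.0,1.8,0.0,1.2,1.2,95.7
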