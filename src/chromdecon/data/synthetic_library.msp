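Name: synthetic-analyte-A (naphthalene-like)
Retention_time: 5.19
Num Peaks: 6
128 999; 127 150; 129 110;
102 80; 64 90; 51 120;

Name: synthetic-analyte-B (organochlorine-like)
Retention_time: 8.50
Num Peaks: 8
100 999; 272 500; 274 480; 237 300;
117 250; 119 240; 65 150; 51 100;

Name: synthetic-analyte-C (organophosphate-like)
Retention_time: 8.51
Num Peaks: 7
285 999; 287 760; 125 640; 109 500;
79 300; 63 220; 47 150;

Name: synthetic-interferent-siloxane
Num Peaks: 4
207 999; 281 700; 355 300; 73 250;

Name: synthetic-analyte-D (phthalate-like)
Retention_time: 11.18
Num Peaks: 5
149 999; 167 300; 279 150; 57 200; 71 180;
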