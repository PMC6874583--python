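subject_id,sex,prev_concussions,days_since_injury_t1,pcss_t1,cdi_t1,trial_accuracy_t1,longitudinal,symptom_resolution,days_since_injury_t2,pcss_t2,cdi_t2,trial_accuracy_t2
1,F,6,36,109,71,94.4,0,,,,,
2,F,0,20,55,68,72.2,1,NSR,225,54,59,41.7
3,F,1,5,54,68,86.1,1,NSR,121,17,68,63.9
4,M,2,23,20,76,77.8,1,SR,86,0,40,61.1
5,M,2,30,64,49,86.1,0,,,,,
6,M,2,7,33,57,5.6,0,,,,,
7,F,2,14,35,46,97.2,1,SR,139,0,40,86.1
8,F,6,8,94,52,66.7,0,,,,,
9,F,1,17,92,67,66.7,1,NSR,79,6,43,58.3
10,F,1,9,67,51,97.2,1,SR,211,0,41,97.2
11,F,1,17,50,46,52.8,1,SR,163,0,42,47.2
12,M,5,14,101,63,69.4,1,NSR,104,54,54,58.3
13,F,1,13,41,43,72.2,0,,,,,
14,F,4,15,24,58,61.1,1,NSR,240,24,63,58.3
15,F,3,30,58,46,75.0,1,NSR,135,11,47,30.6
16,F,0,7,17,43,94.4,1,SR,98,0,40,88.9
17,F,1,8,12,47,80.6,1,SR,85,0,40,77.8
18,M,2,19,46,44,61.1,1,NSR,187,31,49,69.4
19,F,1,12,53,62,8.3,1,NSR,180,20,66,22.2
20,M,1,58,55,49,36.1,0,,,,,
21,F,0,30,59,68,50.0,1,NSR,172,82,76,5.6
22,F,2,39,60,71,66.7,0,,,,,
23,F,2,26,80,67,97.2,1,NSR,174,46,55,91.7
24,F,1,6,55,63,72.2,1,SR,181,0,42,55.6
25,M,1,13,32,46,100.0,1,SR,113,0,49,94.4
26,F,1,48,66,55,88.9,1,NSR,118,3,52,91.7
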