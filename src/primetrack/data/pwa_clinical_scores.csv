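participant_id,wab_aq,wab_fluency,wab_ac,wab_naming,wab_repetition,palpa_swp_pct,navs_vct,navs_vnt,navs_aspt,navs_sppt,navs_sct,cat_written_words_pct,pcb_total_pct
1,93.6,9,10,8.8,10,93,100,81.8,87.5,93.3,93.3,87,97
2,73.6,6,6.4,8.8,7.6,98,100,95.5,96.9,76.7,93.3,80,78
3,92.8,9,10,9.0,9.4,98,100,77.3,100,96.7,100,100,100
4,82.7,6,9.9,8.1,9.4,98,95.5,81.8,96.9,93.3,100,87,100
5,91.7,9,10,8.9,10,100,100,81.8,100,96.7,100,93,98
6,65.3,4,8.5,6.5,7.7,98,100,40.9,56.3,16.7,96.7,87,88
7,81.4,6,8.9,8.6,8.2,93,100,59.1,84.4,56.7,66.7,100,88
8,78.1,5,9.6,7.8,8.7,98,100,50.0,87.5,76.7,96.7,87,93
9,78.9,6,9.7,7.9,6.9,98,100,81.8,87.5,76.7,86.7,87,90
10,77.7,6,7.9,9.2,6.8,93,100,100,93.8,60.0,73.3,93,88
11,63.5,8,6.5,4.4,5.9,80,81.8,50.0,81.3,3.3,66.7,80,63
12,64.5,5,8.0,5.1,6.2,85,90.9,54.6,84.4,16.7,70.0,73,80
13,75.7,4,9.0,7.8,9.1,98,95.5,63.6,93.8,86.7,93.3,93,88
14,92.0,9,9.8,9.4,8.8,98,100,90.9,100,90.0,93.3,87,95
15,93.2,9,9.9,8.8,9.9,100,100,90.9,100,90.0,100,80,95
16,76.3,6,8.0,7.8,8.4,85,90.9,63.6,78.1,16.7,66.7,73,70
17,72.0,5,7.8,7.9,7.3,93,100,72.7,87.5,40.0,70.0,87,77
18,74.6,6,7.4,8.8,7.1,93,90.9,72.7,78.1,63.3,90.0,93,72
19,85.6,6,10,9.1,8.7,98,100,95.5,96.9,96.7,93.3,100,95
20,69.9,4,8.5,8.9,5.6,100,100,81.8,81.3,3.3,53.3,100,72
21,71.4,6,7.6,8.5,5.6,93,95.5,86.4,90.6,10.0,43.3,100,75
22,87.1,6,9.8,9.2,9.6,95,100,100,93.8,96.7,100,93,100
23,79.2,6,9.8,7.5,7.3,98,100,86.4,93.8,60.0,93.3,87,93
24,78.9,6,8.3,8.1,9.1,95,95.5,45.5,87.5,70.0,76.7,80,78
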