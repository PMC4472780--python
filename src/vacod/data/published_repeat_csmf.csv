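reviewer,cause,csmf_original,csmf_repeat,printed_shift
ALL,malaria,13,11,-2
ALL,pneumonia,8,10,2
ALL,meningitis,15,15,0
ALL,diarrhea,9,9,0
ALL,malnutrition,19,12,-7
1,malaria,17,14,-3
1,pneumonia,5,14,9
1,meningitis,12,14,2
1,diarrhea,0,0,0
1,malnutrition,29,14,-15
2,malaria,13,11,-2
2,pneumonia,6.5,4,-2.5
2,meningitis,17,17,0
2,diarrhea,22,22,0
2,malnutrition,13,13,0
3,malaria,6,6,0
3,pneumonia,12,12,0
3,meningitis,19,17,-2
3,diarrhea,6,6,0
3,malnutrition,19,11.5,-7.5
4,malaria,44,33,-11
4,pneumonia,11,11,0
4,meningitis,0,0,0
4,diarrhea,0,0,0
4,malnutrition,11,0,-11
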