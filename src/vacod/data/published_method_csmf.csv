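age_group,site,cause,csmf_mr,csmf_pcva,csmf_nha,csmf_ha,printed_diff_pcva,printed_diff_nha,printed_diff_ha
child,ALL,malaria,12,18,68,12,6,56,0
child,ALL,pneumonia,21,15,26,22,-6,5,1
child,ALL,meningitis,10,10,19,19,0,9,9
child,ALL,diarrhea,13,9,46,15,-4,33,2
child,ALL,malnutrition,16,19,36,21,3,20,5
child,ALL,hiv_aids,7,8,54,7,1,47,0
child,Tororo,malaria,48,38,71,15,-10,23,-33
child,Tororo,pneumonia,20,15,20,18,-5,0,-2
child,Tororo,meningitis,7,10,18,18,3,11,11
child,Tororo,diarrhea,2,5,55,16,3,53,14
child,Tororo,malnutrition,25,20,35,13,-5,10,-12
child,Tororo,hiv_aids,0,8,53,5,-8,53,5
child,Kampala,malaria,10,17,68,12,7,58,2
child,Kampala,pneumonia,10,8,28,22,-2,18,12
child,Kampala,meningitis,10,10,19,19,0,9,9
child,Kampala,diarrhea,14,9,45,16,-5,31,2
child,Kampala,malnutrition,16,19,36,22,3,20,6
child,Kampala,hiv_aids,9,9,54,8,0,45,-1
child,Kisoro,malaria,0,12,65,8,12,65,8
child,Kisoro,pneumonia,40,27,26,20,-13,-14,-20
child,Kisoro,meningitis,14,10,16,16,-4,2,2
child,Kisoro,diarrhea,16,16,45,16,0,29,0
child,Kisoro,malnutrition,10,16,41,27,6,31,17
child,Kisoro,hiv_aids,0,0,49,6,0,49,6
neonate,ALL,septicemia,32,29,82,48,-3,50,16
neonate,ALL,meningitis,22,38,27,18,16,5,-4
neonate,ALL,pneumonia,10,7,12,12,-3,2,2
neonate,ALL,congenital_malformation,6,6,7,7,0,1,1
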