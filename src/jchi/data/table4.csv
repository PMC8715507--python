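residue_id,residue_type,ums_chi1_a,ums_unc_a_minus,ums_unc_a_plus,ums_rmsd_a,ums_rank_a,ums_chi1_b,ums_unc_b_minus,ums_unc_b_plus,ums_rmsd_b,ums_rank_b,tmss_p60,tmss_p180,tmss_pm60,tmss_rmsd,tmst_chi1,tmst_p60,tmst_p180,tmst_pm60,tmst_rmsd,n_j,schmidt_chi1,schmidt_spread,perez_chi1,perez_spread,xray1_chi1,xray1_spread,xray1_n,xray2_chi1,xray2_spread,xray2_n
Val88,VAL,164.6,14,13,1.86,1,-42.4,18,17,1.91,2,13,42,46,0.46,172.8,13,47,40,0.46,5,-10.8,25.7,133.7,25.8,173.4,4.3,4,-57.1,8.3,8
Val144,VAL,166.7,21,20,1.61,1,-35.9,19,18,1.61,2,18,43,39,0.45,163.5,22,49,30,0.42,9,131.9,20.4,133.5,30.7,164.7,3.0,7,-45.6,14.3,6
Leu78,LEU,100.2,20,24,2.50,2,-100.9,24,26,2.30,1,33,26,41,0.78,-90.0,26,31,43,0.60,9,-111.6,30.1,-109.6,44.1,-140.7,11.8,9,-85.4,5.6,4
Ile148,ILE,72.4,13,13,1.46,1,-84.5,16,15,1.55,2,53,8,39,0.45,-72.6,41,8,51,0.42,7,104.3,27.9,99.6,28.8,56.8,10.2,8,-67.7,6.1,4
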