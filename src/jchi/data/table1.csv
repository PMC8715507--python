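residue_id,residue_type,ums_chi1,ums_unc_minus,ums_unc_plus,ums_rmsd,ums_min_rank,tmss_p60,tmss_p180,tmss_pm60,tmss_rmsd,tmst_chi1,tmst_p60,tmst_p180,tmst_pm60,tmst_rmsd,n_j,schmidt_chi1,schmidt_spread,perez_chi1,perez_spread,xray_chi1,xray_spread,xray_n
Val7,VAL,-177.6,8,8,0.80,1,8,87,5,0.51,-174.0,0,86,14,0.50,7,-176.7,30.3,-178.5,25.1,-179.2,5.7,13
Val33,VAL,-179.8,8,8,0.65,1,6,82,12,0.32,-174.3,0,80,20,0.29,9,172.0,32.0,172.5,27.8,-177.4,3.6,13
Val41,VAL,-57.0,8,8,0.62,1,2,13,85,0.41,-61.9,0,16,84,0.41,9,-52.2,32.3,-51.6,24.7,-51.6,7.7,11
Val53,VAL,178.8,7,7,0.54,1,3,90,8,0.35,177.7,6,90,4,0.35,8,166.3,25.5,169.3,21.7,173.9,3.4,13
Val105,VAL,178.3,5,5,0.26,1,0,96,4,0.21,178.7,0,98,2,0.20,8,167.9,20.7,170.1,15.8,178.9,6.6,13
Val120,VAL,-52.9,9,9,0.73,1,1,22,77,0.38,-61.4,0,24,76,0.38,9,-38.9,31.3,-42.3,25.5,-57.1,9.8,10
Val138,VAL,177.0,8,9,0.93,1,2,85,14,0.59,177.7,5,85,10,0.59,7,161.3,23.9,167.0,22.3,164.8,8.6,13
Leu5,LEU,-173.9,9,10,1.30,1,15,81,4,0.80,-165.6,0,78,22,0.69,7,177.8,27.4,-178.2,19.9,177.1,7.6,13
Leu26,LEU,-73.1,8,9,0.92,1,20,0,80,0.55,-73.3,6,9,85,0.43,7,-79.9,14.1,-72.9,0.2,-63.8,5.0,12
Leu46,LEU,-174.0,11,12,1.53,2,18,73,9,0.75,-157.8,0,66,34,0.60,7,173.0,32.8,179.9,27.3,179.0,7.0,13
Leu54,LEU,-61.2,14,12,1.57,1,23,5,72,0.59,-50.5,33,0,67,0.56,6,-63.9,28.1,-59.9,23.2,-57.2,5.3,13
Leu55,LEU,-72.3,11,12,1.47,1,23,0,77,0.89,-64.2,19,0,81,0.87,7,-84.7,0.3,-77.3,0.1,-62.7,8.5,12
Leu67,LEU,-65.0,13,15,1.45,1,14,15,71,0.42,-73.6,4,31,66,0.37,7,-69.7,32.6,-59.1,27.7,-90.3,9.0,12
Leu74,LEU,175.9,9,10,1.24,2,8,75,18,0.52,-169.8,0,70,30,0.46,8,154.2,13.8,159.0,12.5,172.7,5.3,12
Leu112,LEU,-77.4,7,7,0.79,1,22,0,78,0.49,-75.9,4,9,86,0.42,6,-83.4,0.3,-75.8,8.4,-82.1,14.5,13
Leu115,LEU,-69.3,14,16,1.56,1,23,7,71,0.55,-71.3,12,17,71,0.53,7,-77.0,30.5,-63.2,29.2,-70.8,11.5,13
Leu124,LEU,179.0,10,10,1.44,2,8,77,15,0.74,-167.7,0,71,29,0.67,7,159.3,17.8,165.2,15.6,174.5,3.5,13
Ile6,ILE,-64.8,8,8,0.57,1,10,0,90,0.40,-63.3,7,0,93,0.38,7,-57.4,22.5,-57.9,14.6,-59.4,5.1,13
Ile22,ILE,-68.3,6,6,0.30,1,12,0,88,0.34,-67.1,5,0,95,0.18,7,-69.8,20.9,-66.7,15.0,-61.5,8.2,13
Ile65,ILE,-71.6,11,11,0.93,1,32,0,68,0.18,-61.0,31,0,69,0.18,6,-77.4,35.1,-70.9,33.9,-63.9,3.5,11
Ile72,ILE,-67.8,4,4,0.20,1,8,0,92,0.38,-67.8,0,0,100,0.12,5,-68.6,16.1,-66.5,0.2,-66.8,3.0,13
Ile108,ILE,-68.0,7,7,0.44,1,13,0,87,0.38,-66.5,7,0,93,0.28,7,-66.4,22.7,-62.8,16.1,-62.7,3.2,13
Ile119,ILE,-59.8,7,7,0.59,1,1,0,99,0.46,-59.5,1,0,99,0.46,8,-56.1,18.1,-57.5,0.3,-57.2,6.0,13
Ile126,ILE,-66.4,8,9,0.63,1,12,0,88,0.49,-64.4,8,0,92,0.45,8,-67.7,18.6,-67.5,11.0,-64.9,6.3,13
Ile137,ILE,-65.3,6,6,0.43,1,2,0,98,0.43,-65.3,0,0,100,0.32,7,-58.0,0.0,-61.1,0.0,-59.1,3.9,13
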