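patient_id,age,sex,height_cm,weight_kg,creatinine_mgdl,quantity,expected
P1,60.0,M,170.0,72.0,1.0,du_bois_bsa,1.831505
P1,60.0,M,170.0,72.0,1.0,cockcroft_gault,80.000000
P1,60.0,M,170.0,72.0,1.0,jelliffe,66.000000
P1,60.0,M,170.0,72.0,1.0,wright,88.074634
P1,60.0,M,170.0,72.0,1.0,martin,93.229658
P1,60.0,M,170.0,72.0,1.0,mayo,102.966120
P1,60.0,M,170.0,72.0,1.0,mdrd,76.220772
P1,60.0,M,170.0,72.0,1.0,ckd_epi,81.442898
P1,60.0,M,170.0,72.0,1.0,bsa_adj_jelliffe,69.872444
P1,60.0,M,170.0,72.0,1.0,bsa_adj_mayo,109.007492
P1,60.0,M,170.0,72.0,1.0,bsa_adj_mdrd,80.692904
P1,60.0,M,170.0,72.0,1.0,bsa_adj_ckd_epi,86.221429
P1,60.0,M,170.0,72.0,1.0,calvert_auc5_on_cg,525.000000
P2,45.0,F,160.0,55.0,0.7,du_bois_bsa,1.563174
P2,45.0,F,160.0,55.0,0.7,cockcroft_gault,88.120040
P2,45.0,F,160.0,55.0,0.7,jelliffe,100.285714
P2,45.0,F,160.0,55.0,0.7,wright,101.575478
P2,45.0,F,160.0,55.0,0.7,martin,83.261203
P2,45.0,F,160.0,55.0,0.7,mayo,105.153901
P2,45.0,F,160.0,55.0,0.7,mdrd,90.489185
P2,45.0,F,160.0,55.0,0.7,ckd_epi,104.636468
P2,45.0,F,160.0,55.0,0.7,bsa_adj_jelliffe,90.615069
P2,45.0,F,160.0,55.0,0.7,bsa_adj_mayo,95.013811
P2,45.0,F,160.0,55.0,0.7,bsa_adj_mdrd,81.763228
P2,45.0,F,160.0,55.0,0.7,bsa_adj_ckd_epi,94.546275
P2,45.0,F,160.0,55.0,0.7,calvert_auc5_on_cg,565.600198
P3,75.0,M,180.0,95.0,1.8,du_bois_bsa,2.147689
P3,75.0,M,180.0,95.0,1.8,cockcroft_gault,47.646605
P3,75.0,M,180.0,95.0,1.8,jelliffe,30.000000
P3,75.0,M,180.0,95.0,1.8,wright,49.523858
P3,75.0,M,180.0,95.0,1.8,martin,61.100932
P3,75.0,M,180.0,95.0,1.8,mayo,38.866861
P3,75.0,M,180.0,95.0,1.8,mdrd,36.967165
P3,75.0,M,180.0,95.0,1.8,ckd_epi,36.013679
P3,75.0,M,180.0,95.0,1.8,bsa_adj_jelliffe,37.243164
P3,75.0,M,180.0,95.0,1.8,bsa_adj_mayo,48.250829
P3,75.0,M,180.0,95.0,1.8,bsa_adj_mdrd,45.892473
P3,75.0,M,180.0,95.0,1.8,bsa_adj_ckd_epi,44.708778
P3,75.0,M,180.0,95.0,1.8,calvert_auc5_on_cg,363.233025
P4,30.0,F,165.0,80.0,0.5,du_bois_bsa,1.874370
P4,30.0,F,165.0,80.0,0.5,cockcroft_gault,207.777778
P4,30.0,F,165.0,80.0,0.5,jelliffe,162.000000
P4,30.0,F,165.0,80.0,0.5,wright,191.045536
P4,30.0,F,165.0,80.0,0.5,martin,185.789177
P4,30.0,F,165.0,80.0,0.5,mayo,116.550540
P4,30.0,F,165.0,80.0,0.5,mdrd,144.868831
P4,30.0,F,165.0,80.0,0.5,ckd_epi,129.873477
P4,30.0,F,165.0,80.0,0.5,bsa_adj_jelliffe,175.519082
P4,30.0,F,165.0,80.0,0.5,bsa_adj_mayo,126.276814
P4,30.0,F,165.0,80.0,0.5,bsa_adj_mdrd,156.958297
P4,30.0,F,165.0,80.0,0.5,bsa_adj_ckd_epi,140.711565
P4,30.0,F,165.0,80.0,0.5,calvert_auc5_on_cg,1163.888889
P5,82.0,F,150.0,48.0,3.2,du_bois_bsa,1.407862
P5,82.0,F,150.0,48.0,3.2,cockcroft_gault,10.270833
P5,82.0,F,150.0,48.0,3.2,jelliffe,13.612500
P5,82.0,F,150.0,48.0,3.2,wright,14.068809
P5,82.0,F,150.0,48.0,3.2,martin,12.140031
P5,82.0,F,150.0,48.0,3.2,mayo,13.162175
P5,82.0,F,150.0,48.0,3.2,mdrd,13.867388
P5,82.0,F,150.0,48.0,3.2,ckd_epi,12.847022
P5,82.0,F,150.0,48.0,3.2,bsa_adj_jelliffe,11.077756
P5,82.0,F,150.0,48.0,3.2,bsa_adj_mayo,10.711285
P5,82.0,F,150.0,48.0,3.2,bsa_adj_mdrd,11.285182
P5,82.0,F,150.0,48.0,3.2,bsa_adj_ckd_epi,10.454816
P5,82.0,F,150.0,48.0,3.2,calvert_auc5_on_cg,176.354167
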