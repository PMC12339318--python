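sample,cnlc_stage,lifetime_ratio,prothrombin_time_s,total_bilirubin_umol_l,direct_bilirubin_umol_l,indirect_bilirubin_umol_l,alt_u_l,ast_u_l,total_plasma_protein_g_l,albumin_g_l,globulin_g_l,afp_ng_ml
H1,IIA,1.79,13.6,69.7,16.3,53.4,28,38,70.7,39.2,31.5,1079
H2,IB,1.12,15,8.7,4.3,4.4,21,59,52,31.5,20.5,34072
H3,IB,1.38,12,7.1,0.9,6.2,47,43,74.1,43.9,30.2,25.3
H4,IA,1.77,15.7,30,8.6,21.4,23,36,57.3,28.1,29.2,463.1
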