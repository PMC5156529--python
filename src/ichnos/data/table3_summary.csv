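individual,n_measurable,length_mm,length_sd_mm,length_min_mm,length_max_mm,max_width_mm,max_width_sd_mm,max_width_min_mm,max_width_max_mm,foot_index_pct,foot_index_sd,foot_index_min,foot_index_max,step_mm,step_sd_mm,step_min_mm,step_max_mm,stride_mm,stride_sd_mm,stride_min_mm,stride_max_mm,stature_hs_ratio_low_cm,stature_hs_ratio_high_cm,stature_hs_reg_cm,stature_hs_reg_see,stature_aa_low_cm,stature_aa_high_cm,mass_hs_reg_kg,mass_hs_reg_see,mass_aa_low_kg,mass_aa_high_kg,speed_alex_low,speed_alex_high,speed_reg,relspeed_alex_low,relspeed_alex_high,relspeed_reg,width_overestimated
S1,11,261,10.5,245,273,104,3.7,99,111,40.0,1.9,36.6,42.7,568,44.3,505,660,1139,94.0,1044,1284,163,186,171.6,5.4,161,168,53.6,3.7,41.3,48.1,0.47,0.55,0.93,0.25,0.34,0.54,False
S2,1,231,,,,120,,,,51.9,,,,,,,,,,,,144,165,160,5.4,142,149,46.7,3.8,36.5,42.4,,,,,,,True
G1,9,180,,,,79,,,,43.8,,,,416,,,,829,,,,113,129,141.4,5.4,111,116,39.3,3.7,28.5,33.1,0.43,0.50,1.00,0.33,0.44,0.71,False
G2,2,225,,,,117,,,,48.0,,,,453,,,,880,,,,141,161,158.2,5.4,139,145,52.6,3.7,35.6,41.4,0.36,0.42,0.79,0.23,0.30,0.50,False
G3,8,209,,,,85,,,,41.5,,,,433,,,,876,,,,130,149,152.2,5.4,129,135,43.2,3.7,33.1,38.5,0.39,0.46,0.88,0.26,0.35,0.58,False
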