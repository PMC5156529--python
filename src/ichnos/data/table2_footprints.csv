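footprint_id,individual_id,side,order_index,gap_before,length_mm,max_width_mm,foot_index_pct,heel_width_mm,angle_of_gait_deg,stature_hs_ratio_low_cm,stature_hs_ratio_high_cm,stature_hs_reg_cm,stature_aa_low_cm,stature_aa_high_cm,mass_hs_reg_kg,mass_aa_low_kg,mass_aa_high_kg,width_overestimated
TP2/S1-1,S1,right,1,False,271,101,37.2,83,6,170,194,175.4,167,175,53.8,42.9,50.0,False
TP2/S1-2,S1,left,2,False,271,99,36.6,81,4,169,193,175.1,167,175,53.1,42.8,49.8,False
M9/S1-1,S1,left,3,True,250,102,40.6,73,2,156,179,167.5,154,161,51.6,39.6,46.0,False
M9/S1-2,S1,right,4,False,264,105,39.7,80,3,165,189,172.8,163,171,54.2,41.8,48.7,False
M9/S1-3,S1,left,5,False,268,111,41.2,91,4,168,192,174.3,166,173,56.3,42.5,49.4,False
M9/S1-4,S1,right,6,False,245,101,41.2,71,4,153,175,165.6,151,158,50.9,38.8,45.1,False
L8/S1-1,S1,right,7,True,245,104,42.4,78,8,153,175,165.6,151,158,51.7,38.8,45.1,False
L8/S1-2,S1,left,8,False,265,106,40.0,82,11,166,189,173.1,164,171,54.5,41.9,48.8,False
L8/S1-3,S1,right,9,False,260,103,39.6,77,3,163,186,171.3,161,168,53.1,41.2,47.9,False
L8/S1-4,S1,left,10,False,274,106,38.6,81,10,171,196,176.5,169,177,55.6,43.4,50.5,False
L8/S1-5,S1,right,11,False,,,,,,,,,,,,,,False
L8/S1-6,S1,left,12,False,,,,86,3,,,,,,,,,False
L8/S1-7,S1,right,13,False,258,110,42.7,90,8,161,184,170.3,159,166,54.8,40.7,47.4,False
TP2/S2-1,S2,right,1,False,231,120,51.9,86,,144,165,160,142,149,46.7,36.5,42.4,True
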