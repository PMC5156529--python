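taxon,l8,m9,tp2,m10,total
Numididae (?Numida),0,4,0,9,13
Bovidae small (?Madoqua),107,39,16,211,373
Bovidae medium (?Gazella),39,9,10,21,79
Equidae (?Hipparion),1,2,0,0,3
Giraffidae,0,0,0,4,4
Lagomorpha (?Lepus),8,0,0,4,12
Rhinocerotidae,0,1,0,0,1
Unidentified micromammals,0,27,0,17,44
Total,155,82,26,266,529
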