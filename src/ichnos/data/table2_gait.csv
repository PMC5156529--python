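kind,from_id,to_id,from_side,to_side,value_mm
step,TP2/S1-1,TP2/S1-2,right,left,553
step,M9/S1-1,M9/S1-2,left,right,548
step,M9/S1-2,M9/S1-3,right,left,505
step,M9/S1-3,M9/S1-4,left,right,571
step,L8/S1-1,L8/S1-2,right,left,552
step,L8/S1-2,L8/S1-3,left,right,587
step,L8/S1-3,L8/S1-4,right,left,573
step,L8/S1-6,L8/S1-7,left,right,660
stride,M9/S1-1,M9/S1-3,left,left,1044
stride,M9/S1-2,M9/S1-4,right,right,1069
stride,L8/S1-1,L8/S1-3,right,right,1140
stride,L8/S1-2,L8/S1-4,left,left,1159
stride,L8/S1-4,L8/S1-6,left,left,1284
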