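system,mode,occupancy_pct,vdw_mean,vdw_sd,ele_mean,ele_sd,gb_mean,gb_sd,np_mean,np_sd,total_mean,total_sd,consistent
EGFRa-ATP,gray,41.5,-28.0,7.6,-393.7,23.9,372.8,18.7,-7.3,0.3,-56.3,7.7,True
EGFRa-ATP,red,36.4,-31.0,8.5,-394.3,22.9,370.3,17.9,-7.3,0.2,-62.3,7.6,True
EGFRa-ATP,pink,5.2,-23.3,6.0,-357.6,22.8,343.9,15.2,-7.1,0.1,-44.2,8.5,True
EGFRa-ATP,blue,16.9,-27.7,7.7,-372.5,18.4,356.4,14.5,-7.1,0.3,-50.9,6.7,True
ErbB2a-ATP,blue,33.9,-21.2,6.2,-302.0,42.3,285.0,40.4,-6.3,0.2,-44.5,7.1,True
ErbB2a-ATP,lightblue,10.8,-16.5,6.4,-348.9,53.5,341.0,46.0,-6.1,0.2,-30.5,8.2,True
ErbB2a-ATP,gray,3.4,-22.5,6.1,-305.4,14.2,279.9,10.2,-6.5,0.1,-54.5,7.7,True
ErbB2a-ATP,pink,25.5,-20.5,5.8,-444.9,19.3,387.4,15.2,-7.1,0.4,-94.1,7.5,False
ErbB2a-ATP,red,26.4,-19.1,6.4,-420.5,19.5,364.7,16.2,-7.0,0.3,-81.9,8.0,True
EGFRi-FMM,blue,17.6,-74.6,3.5,-34.5,6.9,59.3,5.8,-9.2,0.3,-59.1,3.9,True
EGFRi-FMM,lightblue,39.4,-74.8,4.0,-38.1,5.8,60.2,5.3,-9.1,0.4,-61.9,3.6,True
EGFRi-FMM,gray,19.8,-75.1,3.9,-38.4,5.0,59.0,4.9,-9.0,0.4,-63.5,3.5,True
EGFRi-FMM,pink,10.0,-84.2,3.6,-40.5,6.1,65.9,4.0,-9.6,0.1,-68.4,4.2,True
EGFRi-FMM,red,12.9,-85.7,2.8,-43.9,5.2,68.2,3.6,-9.5,0.1,-71.0,3.9,True
ErbB2i-FMM,lightblue,58.4,-75.7,3.5,-39.8,8.2,60.5,6.8,-9.3,0.5,-64.2,4.1,True
ErbB2i-FMM,blue,24.9,-75.6,3.0,-34.3,5.3,56.8,5.4,-8.8,0.3,-61.9,2.8,True
ErbB2i-FMM,pink,7.6,-75.5,3.2,-40.6,8.6,54.9,7.5,-8.6,0.3,-69.8,4.2,True
ErbB2i-FMM,red,9.0,-78.3,2.8,-46.0,4.7,62.9,4.1,-8.7,0.1,-74.1,3.6,False
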