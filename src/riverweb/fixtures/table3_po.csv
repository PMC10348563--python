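node,ndc,nbc
Abramis brama,0.459,4.631
ASELLIDAE,0.083,0.186
Barbus barbus,0.179,0.761
Bosmina longirostris,0.009,0.005
CAENIS,0.092,0.154
Carassius auratus,0.651,13.593
Chironomidae,0.147,1.244
Culicidae,0.069,0.854
Cyprinus carpio,0.142,0.616
Detritus,0.110,0.188
Diptera,0.110,0.795
Dytiscidae,0.069,0.058
Gammaridae,0.165,1.942
Gymnocephalus cernua,0.115,0.644
Hydracarina,0.064,0.091
Hydrophilidae,0.110,0.058
HYDROPSYCHIDAE,0.115,0.096
Lepomis gibbosus,0.284,1.453
Leptoceridae,0.110,0.276
Moina micrura,0.009,0.005
Ostracoda,0.151,2.503
Perca fluviatilis_ADULTS,0.087,0.615
Phytoplankton,0.193,11.669
POTAMANTHUS,0.087,0.120
Rutilus rutilus,0.454,4.534
Sander lucioperca,0.023,0.105
Scardinius erythrophthalmus,0.115,0.221
Silurus glanis_LARGE,0.028,1.030
Sphaeriidae,0.064,0.526
Unionidae,0.050,0.420
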