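node,ndc,nbc
Abramis brama,0.008,0.156
Asellus sp.,0.004,0
Barbus barbus,0.004,0
Bosmina longirostris,0.008,3.080
Caenis sp.,0.004,0
Carassius auratus,0.008,0.079
Chironomidae,0.029,13.316
Culicidae,0.008,0.004
Cyprinus carpio,0.008,0.729
Detritus,0.050,9.198
Diptera,0.008,0
Dytiscidae,0.004,0
Gammaridae,0.013,0.086
Gymnocephalus cernua,0.038,3.284
Hydracarina,0.004,0
Hydrophilidae,0.004,0
Hydropsyche sp.,0.017,2.296
Lepomis gibbosus,0.004,0
Leptoceridae,0.004,0
Moina micrura,0.004,0
Ostracoda,0.013,0.073
Perca fluviatilis,0.038,7.286
Phytoplankton,0.159,25.632
Potamanthus luteus,0.008,0
Rutilus rutilus,0.025,1.408
Sander lucioperca,0.017,3.727
Scardinius erythrophthalmus,0.021,1.130
Silurus glanis,0.008,0.729
Sphaeriidae,0.004,0
Unionidae,0.008,0.781
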