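label_a,label_b
ASELLIDAE,Asellus sp.
CAENIS,Caenis sp.
HYDROPSYCHIDAE,Hydropsyche sp.
Perca fluviatilis_ADULTS,Perca fluviatilis
POTAMANTHUS,Potamanthus luteus
Silurus glanis_LARGE,Silurus glanis
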