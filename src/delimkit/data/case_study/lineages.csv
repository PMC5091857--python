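lineage,nominal_name,has_morph_data,has_acoustic_data,focal
Scinax_sp1,,true,true,true
Scinax_sp2,,true,true,true
Scinax_sp3,,true,false,true
Scinax_sp4,,true,false,true
Scinax_sp5,,true,false,true
Scinax_sp6,,true,false,true
Scinax_sp7,,true,true,true
Scinax_cruentommus_BRA,Scinax cruentommus,true,true,true
Scinax_aff_cruentommus_BRA,,true,true,true
Scinax_chiquitanus_BRA,Scinax chiquitanus,true,true,true
Scinax_chiquitanus_BOL,Scinax chiquitanus,true,true,false
Scinax_ruber_F1,,false,false,true
Scinax_ruber_F2,,false,false,true
Scinax_ruber_PM,,false,false,true
Scinax_ruber_Peru,Scinax ruber,false,false,false
Scinax_ruber_A,,false,false,false
Scinax_ruber_B,,false,false,false
Scinax_x_signatus,Scinax x-signatus,false,false,false
Scinax_wandae_A,Scinax wandae,true,false,false
Scinax_wandae_B,Scinax wandae,true,false,false
Scinax_fuscomarginatus,Scinax fuscomarginatus,true,true,false
Scinax_madeirae,Scinax madeirae,true,true,false
Scinax_villasboasi,Scinax villasboasi,true,false,false
Scinax_iquitorum,Scinax iquitorum,true,false,false
Scinax_boesemani,Scinax boesemani,true,false,false
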