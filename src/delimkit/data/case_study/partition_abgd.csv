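id,unit,round_assigned
Scinax_sp1,Scinax_sp1,1
Scinax_sp2,Scinax_sp2,1
Scinax_sp3,Scinax_sp3,1
Scinax_sp4,Scinax_sp4,1
Scinax_sp5,Scinax_sp5,1
Scinax_sp6,Scinax_sp6,1
Scinax_sp7,Scinax_sp7,1
Scinax_cruentommus_BRA,Scinax_cruentommus_BRA,1
Scinax_aff_cruentommus_BRA,Scinax_aff_cruentommus_BRA,1
Scinax_chiquitanus_BRA,Scinax_chiquitanus_BRA,1
Scinax_chiquitanus_BOL,Scinax_chiquitanus_BOL,1
Scinax_ruber_F1,Scinax_ruber_F1,1
Scinax_ruber_F2,Scinax_ruber_F2,1
Scinax_ruber_PM,Scinax_ruber_PM,1
Scinax_ruber_Peru,Scinax_ruber_Peru_grp,1
Scinax_ruber_A,Scinax_ruber_Peru_grp,1
Scinax_ruber_B,Scinax_ruber_Peru_grp,1
Scinax_x_signatus,Scinax_ruber_Peru_grp,1
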