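lineage_a,lineage_b,morph_diff,acoustic_diff,reference_split,note
Scinax_sp1,Scinax_sp4,yes,unknown,unknown,body size; supernumerary tubercles; dorsal coloration
Scinax_sp1,Scinax_sp6,yes,unknown,unknown,body size; head proportions; toe I length; vomer processes; coloration
Scinax_sp1,Scinax_wandae_A,yes,unknown,unknown,snout shape; dorsal skin texture; coloration
Scinax_sp1,Scinax_wandae_B,yes,unknown,unknown,dorsal coloration; dorsal skin texture
Scinax_sp1,Scinax_cruentommus_BRA,yes,yes,unknown,morphology plus call duration / pulse rate / dominant frequency
Scinax_sp2,Scinax_fuscomarginatus,yes,yes,unknown,snout shape; tibia coloration; note duration; dominant frequency
Scinax_sp2,Scinax_madeirae,yes,yes,unknown,tibia and infraocular coloration; note duration; dominant frequency
Scinax_sp2,Scinax_villasboasi,yes,unknown,unknown,snout shape; toe lengths; webbing; dorsum and tibia color pattern
Scinax_sp3,Scinax_iquitorum,yes,unknown,unknown,head and foot proportions; dorsal and ventral color pattern
Scinax_sp4,Scinax_sp6,yes,unknown,unknown,body size; supernumerary tubercles; toe webbing
Scinax_sp4,Scinax_wandae_A,yes,unknown,unknown,snout shape; dorsal skin texture; coloration
Scinax_sp4,Scinax_wandae_B,yes,unknown,unknown,dorsal coloration; dorsal skin texture
Scinax_sp4,Scinax_cruentommus_BRA,yes,unknown,unknown,head shape; toe III/IV lengths; perianal skin texture
Scinax_sp5,Scinax_boesemani,yes,unknown,unknown,color pattern of dorsum and venter
Scinax_sp6,Scinax_wandae_A,yes,unknown,unknown,snout shape; dorsal skin texture; coloration
Scinax_sp6,Scinax_wandae_B,yes,unknown,unknown,dorsal coloration; dorsal skin texture
Scinax_sp6,Scinax_cruentommus_BRA,yes,unknown,unknown,finger I tubercles; metatarsal tubercle; canthus rostralis; disc size
Scinax_sp7,Scinax_cruentommus_BRA,unknown,yes,unknown,advertisement-call parameters separate this lineage
Scinax_aff_cruentommus_BRA,Scinax_cruentommus_BRA,no,no,unknown,no morphological or acoustic character separates these lineages
Scinax_chiquitanus_BRA,Scinax_chiquitanus_BOL,no,no,unknown,morphology and advertisement call closely similar across the range
Scinax_ruber_F1,Scinax_ruber_F2,unknown,unknown,unknown,no morphological or bioacoustic material available for comparison
Scinax_ruber_PM,Scinax_ruber_Peru,unknown,unknown,yes,separated by an earlier multi-locus delimitation
Scinax_ruber_PM,Scinax_ruber_A,unknown,unknown,yes,separated by an earlier multi-locus delimitation
Scinax_ruber_PM,Scinax_ruber_B,unknown,unknown,yes,separated by an earlier multi-locus delimitation
Scinax_ruber_PM,Scinax_x_signatus,unknown,unknown,yes,separated by an earlier multi-locus delimitation
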