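kind,id,label,category,species,measured,initial_level,dynamic,isolated,mechanism,fixed,parameters
node,AtorvaEx,atorvastatin (medium),drug_extracellular,atorvastatin,0,0.0,0,0,,,
node,T09Ex,T0901317 (medium),drug_extracellular,T0901317,0,0.0,0,0,,,
node,GWEx,GW3965 (medium),drug_extracellular,GW3965,0,0.0,0,0,,,
node,HC25,25-hydroxycholesterol,stimulus,,0,0.0,0,0,,,
node,siSREBF1,siRNA SREBF1,knockdown_input,,0,0.0,0,0,,,
node,siSREBF2,siRNA SREBF2,knockdown_input,,0,0.0,0,0,,,
node,siLDLR,siRNA LDLR,knockdown_input,,0,0.0,0,0,,,
node,siNPC1,siRNA NPC1,knockdown_input,,0,0.0,0,0,,,
node,siHMGCS1,siRNA HMGCS1,knockdown_input,,0,0.0,0,0,,,
node,CholMedia,medium cholesterol,metabolite_extracellular,cholesterol,0,0.5,0,0,,,
node,SREBP,SREBP precursor,protein,,0,0.5,1,0,,,
node,SREBP1,SREBP1,protein,,0,0.5,1,0,,,
node,SREBP2,SREBP2,protein,,0,0.5,1,0,,,
node,LXR,LXR,protein,,0,0.5,1,0,,,
node,HMGCR,HMGCR,protein,,1,0.5,1,0,,,
node,HMGCS1,HMGCS1,protein,,1,0.5,1,0,,,
node,ACAT2,ACAT2,protein,,1,0.5,1,0,,,
node,ACLY,ACLY,protein,,1,0.5,1,0,,,
node,ACSS2,ACSS2,protein,,1,0.5,1,0,,,
node,MVD,MVD,protein,,1,0.5,1,0,,,
node,IDI1,IDI1,protein,,1,0.5,1,0,,,
node,FDPS,FDPS,protein,,1,0.5,1,0,,,
node,FDFT1,FDFT1,protein,,1,0.5,1,0,,,
node,LSS,LSS,protein,,1,0.5,1,0,,,
node,NSDHL,NSDHL,protein,,1,0.5,1,0,,,
node,FASN,FASN,protein,,1,0.5,1,0,,,
node,ACSL3,ACSL3,protein,,1,0.5,1,0,,,
node,DLAT,DLAT,protein,,1,0.5,1,0,,,
node,ABCA1,ABCA1,protein,,1,0.5,1,0,,,
node,LDLR,LDLR,protein,,0,0.5,1,0,,,
node,NPC1,NPC1,protein,,0,0.5,1,0,,,
node,ACAT2act,ACAT2 activity,activity,,0,0.5,1,0,,,
node,HMGCS1act,HMGCS1 activity,activity,,0,0.5,1,0,,,
node,AcetylCoA,acetyl-CoA,metabolite_intracellular,acetyl-CoA,1,0.5,1,0,,,
node,AcAcCoA,acetoacetyl-CoA,metabolite_intracellular,acetoacetyl-CoA,1,0.5,1,0,,,
node,HMGCoA,HMG-CoA,metabolite_intracellular,HMG-CoA,1,0.5,1,0,,,
node,Mevalonate,mevalonate,metabolite_intracellular,mevalonate,1,0.5,1,0,,,
node,CholER,ER cholesterol,metabolite_intracellular,cholesterol,0,0.5,1,0,,,
node,AtorvaIn,atorvastatin (intracellular),drug_intracellular,atorvastatin,1,0.0,1,0,,,
node,T09In,T0901317 (intracellular),drug_intracellular,T0901317,1,0.0,1,0,,,
node,GWIn,GW3965 (intracellular),drug_intracellular,GW3965,1,0.0,1,0,,,
node,OHAtorvaIn,hydroxy-atorvastatin,drug_intracellular,hydroxy-atorvastatin,1,0.0,1,0,,,
node,AtorvaLactoneIn,atorvastatin lactone,drug_intracellular,atorvastatin-lactone,1,0.0,1,0,,,
node,OHGWIn,hydroxy-GW3965,drug_intracellular,hydroxy-GW3965,1,0.0,1,0,,,
edge,AtorvaEx>AtorvaIn,AtorvaEx>AtorvaIn,,,,,,,hill_regulatory,0,k_AtorvaEx_AtorvaIn;n_AtorvaEx_AtorvaIn
edge,T09Ex>T09In,T09Ex>T09In,,,,,,,hill_regulatory,0,k_T09Ex_T09In;n_T09Ex_T09In
edge,GWEx>GWIn,GWEx>GWIn,,,,,,,hill_regulatory,0,k_GWEx_GWIn;n_GWEx_GWIn
edge,AtorvaIn>OHAtorvaIn,AtorvaIn>OHAtorvaIn,,,,,,,hill_regulatory,0,k_AtorvaIn_OHAtorvaIn;n_AtorvaIn_OHAtorvaIn
edge,AtorvaIn>AtorvaLactoneIn,AtorvaIn>AtorvaLactoneIn,,,,,,,hill_regulatory,0,k_AtorvaIn_AtorvaLactoneIn;n_AtorvaIn_AtorvaLactoneIn
edge,GWIn>OHGWIn,GWIn>OHGWIn,,,,,,,hill_regulatory,0,k_GWIn_OHGWIn;n_GWIn_OHGWIn
edge,CholER~SREBP,CholER~SREBP,,,,,,,hill_regulatory,0,k_CholER_SREBP;n_CholER_SREBP
edge,HC25~SREBP,HC25~SREBP,,,,,,,hill_regulatory,0,k_HC25_SREBP;n_HC25_SREBP
edge,SREBP1~SREBP,SREBP1~SREBP,,,,,,,hill_regulatory,0,k_SREBP1_SREBP;n_SREBP1_SREBP
edge,tf_srebp1,and1,,,,,,,hill_regulatory,1,k_SREBP_SREBP1;n_SREBP_SREBP1;k_siSREBF1_SREBP1;n_siSREBF1_SREBP1
edge,LXR>SREBP1,LXR>SREBP1,,,,,,,hill_regulatory,0,k_LXR_SREBP1;n_LXR_SREBP1
edge,tf_srebp2,and2,,,,,,,hill_regulatory,1,k_SREBP_SREBP2;n_SREBP_SREBP2;k_siSREBF2_SREBP2;n_siSREBF2_SREBP2
edge,T09In>LXR,T09In>LXR,,,,,,,hill_regulatory,0,k_T09In_LXR;n_T09In_LXR
edge,GWIn>LXR,GWIn>LXR,,,,,,,hill_regulatory,0,k_GWIn_LXR;n_GWIn_LXR
edge,SREBP2>HMGCR,SREBP2>HMGCR,,,,,,,hill_regulatory,0,k_SREBP2_HMGCR;n_SREBP2_HMGCR
edge,tf_hmgcs1,and3,,,,,,,hill_regulatory,0,k_SREBP2_HMGCS1;n_SREBP2_HMGCS1;k_siHMGCS1_HMGCS1;n_siHMGCS1_HMGCS1
edge,SREBP2>ACAT2,SREBP2>ACAT2,,,,,,,hill_regulatory,0,k_SREBP2_ACAT2;n_SREBP2_ACAT2
edge,SREBP2>ACLY,SREBP2>ACLY,,,,,,,hill_regulatory,0,k_SREBP2_ACLY;n_SREBP2_ACLY
edge,SREBP2>ACSS2,SREBP2>ACSS2,,,,,,,hill_regulatory,0,k_SREBP2_ACSS2;n_SREBP2_ACSS2
edge,SREBP2>MVD,SREBP2>MVD,,,,,,,hill_regulatory,0,k_SREBP2_MVD;n_SREBP2_MVD
edge,SREBP2>IDI1,SREBP2>IDI1,,,,,,,hill_regulatory,0,k_SREBP2_IDI1;n_SREBP2_IDI1
edge,SREBP2>FDPS,SREBP2>FDPS,,,,,,,hill_regulatory,0,k_SREBP2_FDPS;n_SREBP2_FDPS
edge,SREBP2>FDFT1,SREBP2>FDFT1,,,,,,,hill_regulatory,0,k_SREBP2_FDFT1;n_SREBP2_FDFT1
edge,LXR>FDFT1,LXR>FDFT1,,,,,,,hill_regulatory,0,k_LXR_FDFT1;n_LXR_FDFT1
edge,SREBP2>LSS,SREBP2>LSS,,,,,,,hill_regulatory,0,k_SREBP2_LSS;n_SREBP2_LSS
edge,SREBP2>NSDHL,SREBP2>NSDHL,,,,,,,hill_regulatory,0,k_SREBP2_NSDHL;n_SREBP2_NSDHL
edge,SREBP1>FASN,SREBP1>FASN,,,,,,,hill_regulatory,0,k_SREBP1_FASN;n_SREBP1_FASN
edge,LXR>FASN,LXR>FASN,,,,,,,hill_regulatory,0,k_LXR_FASN;n_LXR_FASN
edge,SREBP1>ACSL3,SREBP1>ACSL3,,,,,,,hill_regulatory,0,k_SREBP1_ACSL3;n_SREBP1_ACSL3
edge,LXR>ACSL3,LXR>ACSL3,,,,,,,hill_regulatory,0,k_LXR_ACSL3;n_LXR_ACSL3
edge,LXR>DLAT,LXR>DLAT,,,,,,,hill_regulatory,0,k_LXR_DLAT;n_LXR_DLAT
edge,LXR>ABCA1,LXR>ABCA1,,,,,,,hill_regulatory,0,k_LXR_ABCA1;n_LXR_ABCA1
edge,tf_ldlr,and4,,,,,,,hill_regulatory,0,k_SREBP2_LDLR;n_SREBP2_LDLR;k_siLDLR_LDLR;n_siLDLR_LDLR
edge,tf_npc1,and5,,,,,,,hill_regulatory,0,k_SREBP2_NPC1;n_SREBP2_NPC1;k_siNPC1_NPC1;n_siNPC1_NPC1
edge,ACAT2>ACAT2act,ACAT2>ACAT2act,,,,,,,hill_regulatory,0,k_ACAT2_ACAT2act;n_ACAT2_ACAT2act
edge,HMGCS1>HMGCS1act,HMGCS1>HMGCS1act,,,,,,,hill_regulatory,0,k_HMGCS1_HMGCS1act;n_HMGCS1_HMGCS1act
edge,R_k1,AcetylCoA>AcetylCoA,,,,,,,mass_action,0,k1
edge,R_k2,and6,,,,,,,mass_action,0,k2
edge,R_k3,and7,,,,,,,mass_action,0,k3
edge,R_k4,and8,,,,,,,michaelis_menten_inhibited,0,k4;kM4;kI_atorvastatin
edge,R_k5,Mevalonate>CholER,,,,,,,mass_action,0,k5
edge,R_k6,and9,,,,,,,uptake_product,0,k6
edge,R_k7,AcetylCoA~AcetylCoA,,,,,,,mass_action,0,k7
edge,R_k8,CholER~CholER,,,,,,,mass_action,0,k8
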