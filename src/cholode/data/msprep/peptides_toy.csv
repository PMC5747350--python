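precursor,protein,is_decoy,proteotypic,m_score,run,condition,bio_rep,intensity,rt
PA_pep00,PA,False,True,1e-06,r1,A,1,1000.0,100.0
PA_pep01,PA,False,True,1e-06,r1,A,1,950.0,101.0
PA_pep02,PA,False,True,1e-06,r1,A,1,900.0,102.0
PA_pep03,PA,False,True,1e-06,r1,A,1,850.0,103.0
PA_pep04,PA,False,True,1e-06,r1,A,1,800.0,104.0
PA_pep05,PA,False,True,1e-06,r1,A,1,750.0,105.0
PA_pep06,PA,False,True,1e-06,r1,A,1,700.0,106.0
PA_pep07,PA,False,True,1e-06,r1,A,1,650.0,107.0
PA_pep08,PA,False,True,1e-06,r1,A,1,600.0,108.0
PA_pep09,PA,False,True,1e-06,r1,A,1,550.0,109.0
PB_pep0,PB,False,True,1e-06,r1,A,1,400.0,200.0
PB_pep1,PB,False,True,1e-06,r1,A,1,401.0,201.0
PB_pep2,PB,False,True,1e-06,r1,A,1,402.0,202.0
PC_shared,PC,False,False,1e-06,r1,A,1,9000.0,300.0
PC_pep1,PC,False,True,1e-06,r1,A,1,120.0,301.0
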