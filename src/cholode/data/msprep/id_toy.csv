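precursor,protein,is_decoy,proteotypic,m_score,run,condition,bio_rep,intensity,rt
p1,prot0,False,True,0.05,r1,A,1,1000.0,600.0
p2,prot1,False,True,5e-06,r1,A,1,2000.0,1200.0
p3,prot2,False,True,5e-06,r1,A,1,3000.0,1800.0
p4,prot3,False,True,0.05,r1,A,1,4000.0,2400.0
p5,prot4,False,True,5e-06,r1,A,1,5000.0,3000.0
p1,prot0,False,True,0.05,r2,A,2,1000.0,600.0
p2,prot1,False,True,0.05,r2,A,2,2000.0,1200.0
p3,prot2,False,True,0.05,r2,A,2,3000.0,1800.0
p4,prot3,False,True,0.05,r2,A,2,4000.0,2400.0
p5,prot4,False,True,5e-06,r2,A,2,5000.0,3000.0
p1,prot0,False,True,0.05,r3,A,3,1000.0,600.0
p2,prot1,False,True,0.05,r3,A,3,2000.0,1200.0
p3,prot2,False,True,0.05,r3,A,3,3000.0,1800.0
p4,prot3,False,True,0.05,r3,A,3,4000.0,2400.0
p5,prot4,False,True,5e-06,r3,A,3,5000.0,3000.0
p1,prot0,False,True,0.05,r4,B,1,1000.0,600.0
p2,prot1,False,True,0.05,r4,B,1,2000.0,1200.0
p3,prot2,False,True,5e-06,r4,B,1,3000.0,1800.0
p4,prot3,False,True,5e-06,r4,B,1,4000.0,2400.0
p5,prot4,False,True,5e-06,r4,B,1,5000.0,3000.0
p1,prot0,False,True,0.05,r5,B,2,1000.0,600.0
p2,prot1,False,True,0.05,r5,B,2,2000.0,1200.0
p3,prot2,False,True,0.05,r5,B,2,3000.0,1800.0
p4,prot3,False,True,5e-06,r5,B,2,4000.0,2400.0
p5,prot4,False,True,5e-06,r5,B,2,5000.0,3000.0
p1,prot0,False,True,0.05,r6,B,3,1000.0,600.0
p2,prot1,False,True,0.05,r6,B,3,2000.0,1200.0
p3,prot2,False,True,0.05,r6,B,3,3000.0,1800.0
p4,prot3,False,True,5e-06,r6,B,3,4000.0,2400.0
p5,prot4,False,True,5e-06,r6,B,3,5000.0,3000.0
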