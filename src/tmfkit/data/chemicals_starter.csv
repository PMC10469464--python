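name,class,chain_length,molar_mass,molar_volume_cm3_mol,melting_point_K,water_solubility_mol_m3,logD_NLW,logD_PLW,logD_ALBW,logD_SPW,logD_NLW_source,logD_PLW_source,logD_ALBW_source,logD_SPW_source
PFBA,PFCA,4,214.04,168.0,265.0,300.0,,,,,,,,
PFPeA,PFCA,5,264.05,191.0,278.0,150.0,,,,,,,,
PFHxA,PFCA,6,314.05,214.0,287.0,60.0,,,,,,,,
PFHpA,PFCA,7,364.06,237.0,303.0,30.0,,,,,,,,
PFOA,PFCA,8,414.07,260.0,327.0,23.0,-0.8,3.45,4.10,2.00,exp_37C,exp_37C,exp_37C,exp_37C
PFNA,PFCA,9,464.08,283.0,332.0,7.0,-0.6,3.80,4.30,2.20,exp_37C,exp_37C,exp_37C,exp_37C
PFDA,PFCA,10,514.08,306.0,351.0,2.0,-0.4,4.15,4.55,2.40,exp_37C,exp_37C,exp_37C,exp_37C
PFUdA,PFCA,11,564.09,329.0,356.0,0.5,-0.2,4.50,4.70,2.60,exp_37C,exp_37C,exp_37C,exp_37C
PFDoA,PFCA,12,614.10,352.0,380.0,0.1,,,,,,,,
PFTrDA,PFCA,13,664.10,375.0,398.0,0.03,,,,,,,,
PFTeDA,PFCA,14,714.11,398.0,403.0,0.01,,,,,,,,
PFHxDA,PFCA,16,814.12,444.0,410.0,0.001,,,,,,,,
PFBS,PFSA,4,300.10,213.0,349.0,180.0,-1.5,2.40,3.30,1.40,exp_37C,exp_37C,exp_37C,exp_37C
PFHxS,PFSA,6,400.11,259.0,460.0,25.0,-1.1,3.00,3.80,1.80,exp_37C,exp_37C,exp_37C,exp_37C
PFOS,PFSA,8,500.13,305.0,527.0,1.4,-0.7,3.75,4.40,2.30,exp_37C,exp_37C,exp_37C,exp_37C
PFDS,PFSA,10,600.14,351.0,420.0,0.1,,,,,,,,
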