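species,center_cm1,fwhm_cm1,rel_amplitude,shape,assignment,context
Amanita_rubescens,2925,10,0.6,lorentzian,lipid CH2 asymmetric stretch,core
Amanita_rubescens,1633,16,1.0,lorentzian,amide I beta-sheet,core
Amanita_rubescens,1548,10,0.35,lorentzian,amide II alpha-helix,core
Amanita_rubescens,1542,10,0.35,lorentzian,amide II alpha-helix,core
Amanita_rubescens,1515,10,0.4,lorentzian,amide II tyrosine ring,core
Amanita_rubescens,1451,10,0.4,lorentzian,lipid CH2/CH3 asymmetric bending,core
Amanita_rubescens,1373,10,0.4,lorentzian,chitin,core
Amanita_rubescens,1370,10,0.3,lorentzian,lipid carboxylate/CH deformation,core
Amanita_rubescens,1161,10,0.3,lorentzian,glycogen C-O shoulder,core
Amanita_rubescens,1154,10,0.45,lorentzian,chitin,core
Amanita_rubescens,1090,16,0.35,lorentzian,beta-1-3-glucan shoulder (shifted),core
Amanita_rubescens,1031,16,0.8,lorentzian,beta-1-3-glucan,core
Amanita_rubescens,1003,10,0.5,lorentzian,chitin,core
Amanita_rubescens,990,10,0.25,lorentzian,mannan shoulder,core
Amanita_rubescens,976,10,0.25,lorentzian,mannan shoulder,core
Amanita_rubescens,1544,10,0.35,lorentzian,protein CH3/CH2 bending (mixed stand),mixed_add
Amanita_rubescens,1372,10,0.3,lorentzian,protein CH3/CH2 bending (mixed stand),mixed_add
Amanita_rubescens,1407,10,0.3,lorentzian,beech-stand marker,mono_add
Xerocomus_pruinatus,2925,10,0.6,lorentzian,lipid CH2 asymmetric stretch,core
Xerocomus_pruinatus,1630,16,1.0,lorentzian,amide I beta-sheet,core
Xerocomus_pruinatus,1548,10,0.35,lorentzian,amide II alpha-helix,core
Xerocomus_pruinatus,1542,10,0.35,lorentzian,amide II alpha-helix,core
Xerocomus_pruinatus,1515,10,0.4,lorentzian,amide II tyrosine ring,core
Xerocomus_pruinatus,1451,10,0.4,lorentzian,lipid CH2/CH3 asymmetric bending,core
Xerocomus_pruinatus,1373,10,0.4,lorentzian,chitin,core
Xerocomus_pruinatus,1161,10,0.3,lorentzian,glycogen C-O shoulder,core
Xerocomus_pruinatus,1154,10,0.45,lorentzian,chitin,core
Xerocomus_pruinatus,1075,16,0.35,lorentzian,beta-1-3-glucan shoulder,core
Xerocomus_pruinatus,1031,16,0.8,lorentzian,beta-1-3-glucan,core
Xerocomus_pruinatus,1003,10,0.5,lorentzian,chitin,core
Xerocomus_pruinatus,990,10,0.25,lorentzian,mannan shoulder,core
Xerocomus_pruinatus,976,10,0.25,lorentzian,mannan shoulder,core
Xerocomus_pruinatus,1313,10,0.3,lorentzian,protein CH3/CH2 bending (mixed stand),mixed_add
Russula_ochroleuca,2925,10,0.6,lorentzian,lipid CH2 asymmetric stretch,core
Russula_ochroleuca,2850,10,0.5,lorentzian,lipid CH2 symmetric stretch,core
Russula_ochroleuca,1740,10,0.4,lorentzian,lipid C=O stretch,core
Russula_ochroleuca,1649,16,0.4,lorentzian,amide I random coil,core
Russula_ochroleuca,1627,16,0.85,lorentzian,amide I beta-sheet,core
Russula_ochroleuca,1618,16,0.4,lorentzian,amide I beta-sheet,core
Russula_ochroleuca,1515,10,0.4,lorentzian,amide II tyrosine ring,core
Russula_ochroleuca,1451,10,0.4,lorentzian,lipid CH2/CH3 asymmetric bending,core
Russula_ochroleuca,1373,10,0.4,lorentzian,chitin,core
Russula_ochroleuca,1370,10,0.3,lorentzian,lipid carboxylate/CH deformation,core
Russula_ochroleuca,1154,10,0.45,lorentzian,chitin,core
Russula_ochroleuca,1153,10,0.3,lorentzian,glycogen C-O shoulder,core
Russula_ochroleuca,1075,16,0.35,lorentzian,beta-1-3-glucan shoulder,core
Russula_ochroleuca,1031,16,0.8,lorentzian,beta-1-3-glucan,core
Russula_ochroleuca,1003,10,0.5,lorentzian,chitin,core
Russula_ochroleuca,990,10,0.25,lorentzian,mannan shoulder,core
Russula_ochroleuca,976,10,0.25,lorentzian,mannan shoulder,core
Lactarius_subdulcis,2925,10,0.6,lorentzian,lipid CH2 asymmetric stretch,core
Lactarius_subdulcis,2850,10,0.5,lorentzian,lipid CH2 symmetric stretch,core
Lactarius_subdulcis,1740,10,0.4,lorentzian,lipid C=O stretch,core
Lactarius_subdulcis,1632,16,1.0,lorentzian,amide I beta-sheet,core
Lactarius_subdulcis,1515,10,0.4,lorentzian,amide II tyrosine ring,core
Lactarius_subdulcis,1451,10,0.4,lorentzian,lipid CH2/CH3 asymmetric bending,core
Lactarius_subdulcis,1373,10,0.4,lorentzian,chitin,core
Lactarius_subdulcis,1370,10,0.3,lorentzian,lipid carboxylate/CH deformation,core
Lactarius_subdulcis,1154,10,0.45,lorentzian,chitin,core
Lactarius_subdulcis,1153,10,0.3,lorentzian,glycogen C-O shoulder,core
Lactarius_subdulcis,1075,16,0.35,lorentzian,beta-1-3-glucan shoulder,core
Lactarius_subdulcis,1031,16,0.8,lorentzian,beta-1-3-glucan,core
Lactarius_subdulcis,1003,10,0.5,lorentzian,chitin,core
Lactarius_subdulcis,990,10,0.25,lorentzian,mannan shoulder,core
Lactarius_subdulcis,976,10,0.25,lorentzian,mannan shoulder,core
Cenococcum_geophilum,2925,10,0.6,lorentzian,lipid CH2 asymmetric stretch,core
Cenococcum_geophilum,1617,16,1.0,lorentzian,amide I beta-sheet (shifted),core
Cenococcum_geophilum,1515,10,0.4,lorentzian,amide II tyrosine ring,core
Cenococcum_geophilum,1451,10,0.4,lorentzian,lipid CH2/CH3 asymmetric bending,core
Cenococcum_geophilum,1373,10,0.4,lorentzian,chitin,core
Cenococcum_geophilum,1370,10,0.3,lorentzian,lipid carboxylate/CH deformation,core
Cenococcum_geophilum,1154,10,0.45,lorentzian,chitin,core
Cenococcum_geophilum,1153,10,0.3,lorentzian,glycogen C-O shoulder,core
Cenococcum_geophilum,1108,10,0.8,lorentzian,polysaccharide C-O vibration,core
Cenococcum_geophilum,1075,16,0.35,lorentzian,beta-1-3-glucan shoulder,core
Cenococcum_geophilum,1031,16,0.8,lorentzian,beta-1-3-glucan,core
Cenococcum_geophilum,1003,10,0.5,lorentzian,chitin,core
Cenococcum_geophilum,831,10,0.6,lorentzian,mannan marker,core
Cenococcum_geophilum,2363,10,0.3,lorentzian,supplementary band (mixed stand),mixed_add
Cenococcum_geophilum,1663,16,0.4,lorentzian,amide I supplementary (mixed stand),mixed_add
Cenococcum_geophilum,1453,10,0.4,lorentzian,protein CH3/CH2 bending (mixed stand),mixed_add
Cenococcum_geophilum,1372,10,0.4,lorentzian,protein CH3/CH2 bending (mixed stand),mixed_add
Cenococcum_geophilum,830,10,0.4,lorentzian,mannan marker (mixed stand),mixed_add
Cenococcum_geophilum,1451,10,0.4,lorentzian,absent in mono-stand samples,mono_remove
Cenococcum_geophilum,1373,10,0.4,lorentzian,absent in mono-stand samples,mono_remove
Cenococcum_geophilum,1370,10,0.3,lorentzian,absent in mono-stand samples,mono_remove
Cenococcum_geophilum,831,10,0.4,lorentzian,absent in mono-stand samples,mono_remove
Cenococcum_geophilum,1621,16,0.4,lorentzian,protein beta-sheet (Swabian),swabian_add
Cenococcum_geophilum,1234,10,0.3,lorentzian,asymmetric P-H stretch (Swabian),swabian_add
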