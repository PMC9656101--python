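label,composition,implication,note
C2H7N,C2H7N,quaternary,isoquinoline ring opening ejecting N plus two methyls; hallmark of the alkaloid family
CH3NH2,CH5N,tertiary,methylamine loss from an N-methyl tertiary amine
NH3,NH3,secondary,ammonia loss from a secondary (NH) amine
NH,NH,N_acyl_or_oxo,NH loss reported for oxoaporphines
C2H5NO,C2H5NO,N_acyl_or_oxo,acetamide-side loss from an N-acetyl substituent
CH3OH,CH4O,generic,methanol loss from an aryl methoxy
CH3O,CH3O,generic,methoxy radical loss
CO,CO,generic,carbonyl extrusion
H2O,H2O,generic,water loss from a hydroxyl
CH3,CH3,generic,methyl radical loss
CH2O,CH2O,generic,formaldehyde loss (methylenedioxy or methoxy)
C2H7N+CH3,C3H10N,generic,cumulative ring-opening plus methyl loss
C2H7N+CH3OH,C3H11NO,generic,cumulative ring-opening plus methanol loss
C2H7N+CH3OH+CO,C4H11NO2,generic,cumulative ring-opening plus methanol plus CO
CH3NH2+CH3OH,C2H9NO,generic,cumulative methylamine plus methanol loss
CH3NH2+CH3OH+CO,C3H9NO2,generic,cumulative methylamine plus methanol plus CO
CH3NH2+CH2O,C2H7NO,generic,cumulative methylamine plus formaldehyde loss
CH3NH2+CH2O+CO,C3H7NO2,generic,cumulative methylamine plus formaldehyde plus CO
NH3+CH3,CH6N,generic,cumulative ammonia plus methyl loss
NH3+CH3O,CH6NO,generic,cumulative ammonia plus methoxy loss
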