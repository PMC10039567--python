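name,dimension
MaxAbsEStateIndex,2
MaxEStateIndex,2
MinAbsEStateIndex,2
MinEStateIndex,2
qed,1
SPS,2
MolWt,1
HeavyAtomMolWt,1
ExactMolWt,1
NumValenceElectrons,1
NumRadicalElectrons,1
FpDensityMorgan1,2
FpDensityMorgan2,2
FpDensityMorgan3,2
BalabanJ,2
BertzCT,2
Chi0,2
Chi0n,2
Chi0v,2
Chi1,2
Chi1n,2
Chi1v,2
Chi2n,2
Chi2v,2
Chi3n,2
Chi3v,2
Chi4n,2
Chi4v,2
HallKierAlpha,2
Kappa1,2
Kappa2,2
Kappa3,2
LabuteASA,2
PEOE_VSA1,2
PEOE_VSA10,2
PEOE_VSA11,2
PEOE_VSA12,2
PEOE_VSA13,2
PEOE_VSA14,2
PEOE_VSA2,2
PEOE_VSA3,2
PEOE_VSA4,2
PEOE_VSA5,2
PEOE_VSA6,2
PEOE_VSA7,2
PEOE_VSA8,2
PEOE_VSA9,2
SMR_VSA1,2
SMR_VSA10,2
SMR_VSA2,2
SMR_VSA3,2
SMR_VSA4,2
SMR_VSA5,2
SMR_VSA6,2
SMR_VSA7,2
SMR_VSA8,2
SMR_VSA9,2
SlogP_VSA1,2
SlogP_VSA10,2
SlogP_VSA11,2
SlogP_VSA12,2
SlogP_VSA2,2
SlogP_VSA3,2
SlogP_VSA4,2
SlogP_VSA5,2
SlogP_VSA6,2
SlogP_VSA7,2
SlogP_VSA8,2
SlogP_VSA9,2
TPSA,1
EState_VSA1,2
EState_VSA10,2
EState_VSA11,2
EState_VSA2,2
EState_VSA3,2
EState_VSA4,2
EState_VSA5,2
EState_VSA6,2
EState_VSA7,2
EState_VSA8,2
EState_VSA9,2
VSA_EState1,2
VSA_EState10,2
VSA_EState2,2
VSA_EState3,2
VSA_EState4,2
VSA_EState5,2
VSA_EState6,2
VSA_EState7,2
VSA_EState8,2
VSA_EState9,2
FractionCSP3,1
HeavyAtomCount,1
NHOHCount,1
NOCount,1
NumAliphaticCarbocycles,2
NumAliphaticHeterocycles,2
NumAliphaticRings,2
NumAromaticCarbocycles,2
NumAromaticHeterocycles,2
NumAromaticRings,2
NumHAcceptors,1
NumHDonors,1
NumHeteroatoms,1
NumRotatableBonds,1
NumSaturatedCarbocycles,1
NumSaturatedHeterocycles,1
NumSaturatedRings,1
RingCount,1
MolLogP,1
MolMR,1
fr_Al_COO,1
fr_Al_OH,1
fr_Al_OH_noTert,1
fr_ArN,1
fr_Ar_COO,1
fr_Ar_N,1
fr_Ar_NH,1
fr_Ar_OH,1
fr_COO,1
fr_COO2,1
fr_C_O,1
fr_C_O_noCOO,1
fr_C_S,1
fr_HOCCN,1
fr_Imine,1
fr_NH0,1
fr_NH1,1
fr_NH2,1
fr_N_O,1
fr_Ndealkylation1,1
fr_Ndealkylation2,1
fr_Nhpyrrole,1
fr_SH,1
fr_aldehyde,1
fr_alkyl_carbamate,1
fr_alkyl_halide,1
fr_allylic_oxid,1
fr_amide,1
fr_amidine,1
fr_aniline,1
fr_aryl_methyl,1
fr_azide,1
fr_azo,1
fr_barbitur,1
fr_benzene,1
fr_benzodiazepine,1
fr_bicyclic,1
fr_diazo,1
fr_dihydropyridine,1
fr_epoxide,1
fr_ester,1
fr_ether,1
fr_furan,1
fr_guanido,1
fr_halogen,1
fr_hdrzine,1
fr_hdrzone,1
fr_imidazole,1
fr_imide,1
fr_isocyan,1
fr_isothiocyan,1
fr_ketone,1
fr_ketone_Topliss,1
fr_lactam,1
fr_lactone,1
fr_methoxy,1
fr_morpholine,1
fr_nitrile,1
fr_nitro,1
fr_nitro_arom,1
fr_nitro_arom_nonortho,1
fr_nitroso,1
fr_oxazole,1
fr_oxime,1
fr_para_hydroxylation,1
fr_phenol,1
fr_phenol_noOrthoHbond,1
fr_phos_acid,1
fr_phos_ester,1
fr_piperdine,1
fr_piperzine,1
fr_priamide,1
fr_prisulfonamd,1
fr_pyridine,1
fr_quatN,1
fr_sulfide,1
fr_sulfonamd,1
fr_sulfone,1
fr_term_acetylene,1
fr_tetrazole,1
fr_thiazole,1
fr_thiocyan,1
fr_thiophene,1
fr_unbrch_alkane,1
fr_urea,1
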