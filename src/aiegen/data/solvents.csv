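name,smiles,synonyms
water,O,h2o
methanol,CO,meoh
ethanol,CCO,etoh
isopropanol,CC(C)O,ipa;2-propanol;isopropyl alcohol
n-butanol,CCCCO,butanol;1-butanol
acetone,CC(C)=O,propanone
acetonitrile,CC#N,acn;mecn
dimethyl sulfoxide,CS(C)=O,dmso
"n,n-dimethylformamide",CN(C)C=O,dmf;dimethylformamide
"n,n-dimethylacetamide",CC(=O)N(C)C,dmac;dimethylacetamide
n-methylpyrrolidone,CN1CCCC1=O,nmp
tetrahydrofuran,C1CCOC1,thf
"1,4-dioxane",C1COCCO1,dioxane
diethyl ether,CCOCC,ether;et2o
ethyl acetate,CCOC(C)=O,ea;etoac
dichloromethane,ClCCl,dcm;methylene chloride
chloroform,ClC(Cl)Cl,trichloromethane;chcl3
"1,2-dichloroethane",ClCCCl,dce
toluene,Cc1ccccc1,
benzene,c1ccccc1,
pyridine,c1ccncc1,
n-hexane,CCCCCC,hexane
cyclohexane,C1CCCCC1,
glycerol,OCC(O)CO,glycerin
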