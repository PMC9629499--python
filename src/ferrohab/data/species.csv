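name,formula,charge,phase,dGf0_kJ_mol,dHf0_kJ_mol,source
H2O,H2O,0,liquid-water,-237.18,-285.83,"Wagman et al. (1982) NBS tables"
H+,H,1,aqueous,0.0,0.0,"convention (ionic reference)"
Fe2+,Fe,2,aqueous,-78.90,-89.10,"Wagman et al. (1982) NBS tables"
Fe3+,Fe,3,aqueous,-4.70,-48.50,"Wagman et al. (1982) NBS tables"
acetate,C2H3O2,-1,aqueous,-369.31,-486.01,"Wagman et al. (1982) NBS tables"
HCO3-,CHO3,-1,aqueous,-586.77,-691.99,"Wagman et al. (1982) NBS tables"
H2(aq),H2,0,aqueous,17.72,-4.04,"Amend & Shock (2001) FEMS Microbiol Rev 25:175"
goethite,FeHO2,0,solid,-488.6,-559.3,"Robie & Hemingway (1995) USGS Bull 2131"
hematite,Fe2O3,0,solid,-742.2,-824.2,"Robie & Hemingway (1995) USGS Bull 2131"
ferrihydrite,FeH3O3,0,solid,-696.5,-823.0,"Wagman et al. (1982) NBS tables, Fe(OH)3 (precipitated)"
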