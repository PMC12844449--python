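id,rt_min,formula,mz,reactions,product_ions
parent,8.21,C19H27FN4O2,363.2191,,145.0396;233.1085;251.1190;318.1976
M1,5.56,C19H27FN4O4,395.2089,hydroxylation:side_chain;hydroxylation:side_chain,145.0396;163.0502;267.1140;378.1824
M2,5.62,C19H28N4O4,377.2183,defluor_oh:side_chain;hydroxylation:side_chain,145.0396;229.0972;247.1077;332.1969;360.1918
M3,5.67,C19H28N4O4,377.2183,hydroxylation:adb_residue;defluor_oh:side_chain,145.0396;213.1022;231.1128;360.1918
M4,5.72,C19H28N4O4,377.2183,defluor_oh:side_chain;hydroxylation:side_chain,145.0396;229.0972;247.1077;332.1969;360.1918
M5,5.77,C19H26N4O4,375.2027,hydroxylation:adb_residue;dehydrogenation:adb_residue;defluor_oh:side_chain,145.0396;213.1022;231.1128;357.1921
M6,6.05,C19H28N4O4,377.2183,hydroxylation:core;defluor_oh:side_chain,161.0346;179.0451;229.0972;247.1077;332.1969
M7,6.08,C19H26N4O4,375.2027,dehydrogenation:adb_residue;defluor_oh:side_chain;hydroxylation:side_chain,145.0396;229.0972;245.0921;330.1812;358.1761
M8,6.30,C19H26N4O4,375.2027,hydroxylation:adb_residue;defluor_aldehyde:side_chain,145.0396;163.0502;201.1022;330.1812;358.1761
M9,6.38,C19H24N4O4,373.1870,oxidation_aldehyde:adb_residue;dehydrogenation:adb_residue;defluor_oh:side_chain,145.0396;163.0502;213.1022;231.1128
M10,6.57,C19H27FN4O3,379.2140,hydroxylation:side_chain,145.0396;231.0928;249.1034;267.1140;334.1925
M11,6.59,C19H26N4O4,375.2027,defluor_cooh:side_chain,145.0396;217.0972;245.0921;330.1812;358.1761
M12,6.64,C19H27FN4O3,379.2140,hydroxylation:side_chain,145.0396;231.0928;249.1034;267.1140;334.1925
M13,6.66,C19H28N4O3,361.2234,defluor_oh:side_chain,145.0396;213.1022;231.1128;316.2020;344.1969
M14,6.69,C19H27FN4O3,379.2140,hydroxylation:side_chain,145.0396;231.0928;249.1034;267.1140;334.1925
M15,6.90,C19H27FN4O3,379.2140,hydroxylation:side_chain,145.0396;231.0928;249.1034;267.1140;334.1925
M16,7.08,C19H25N3O4,360.1918,amide_hydrolysis:adb_residue;dehydrogenation:adb_residue;defluor_oh:side_chain,145.0396;163.0502;213.1021;231.1128;360.1918
M17,7.12,C19H27FN4O3,379.2140,hydroxylation:side_chain,145.0396;233.1085;251.1190;362.1874
M18,7.29,C19H27N3O4,362.2074,amide_hydrolysis:adb_residue;defluor_oh:side_chain,145.0396;213.1022;231.1128;316.2020
M19,7.42,C19H27FN4O3,379.2140,hydroxylation:core,161.0346;179.0451;249.1034;267.1140;334.1925
M20,7.54,C19H26FN3O4,380.1980,amide_hydrolysis:adb_residue;hydroxylation:side_chain,145.0396;251.1190;304.1820;362.1874
M21,8.04,C19H26FN3O4,380.1980,deamination:adb_residue;hydroxylation:core,161.0346;179.0451;229.0972;267.1140;334.1925
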