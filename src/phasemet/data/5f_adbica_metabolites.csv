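id,rt_min,formula,mz,reactions,product_ions
parent,7.95,C20H28FN3O2,362.2238,,144.0444;232.1132;345.1973
M1,5.37,C20H28FN3O4,394.2137,hydroxylation:core;hydroxylation:side_chain,160.0393;264.1031;377.1871
M2,5.39,C20H29N3O4,376.2231,hydroxylation:core;defluor_oh:side_chain,160.0393;246.1125
M3,5.49,C20H28FN3O4,394.2137,hydroxylation:core;hydroxylation:side_chain,160.0393;264.1031;377.1871
M4,5.52,C20H29N3O4,376.2231,hydroxylation:core;defluor_oh:side_chain,160.0393;246.1125;359.1965
M5,5.53,C20H28FN3O4,394.2137,hydroxylation:adb_residue;hydroxylation:side_chain,144.0444;248.1081;377.1871
M6,5.60,C20H28FN3O4,394.2137,hydroxylation:core;hydroxylation:side_chain,160.0393;264.1031;377.1871
M7,5.61,C20H29N3O4,376.2231,defluor_oh:side_chain;hydroxylation:side_chain,144.0444;246.1125;359.1965
M8,5.66,C20H29N3O4,376.2231,hydroxylation:adb_residue;defluor_oh:side_chain,144.0444;230.1176;359.1965
M9,5.69,C20H28FN3O4,394.2137,hydroxylation:adb_residue;hydroxylation:side_chain,144.0444;248.1081;377.1871
M10,5.72,C20H27N3O4,374.2074,dehydrogenation:adb_residue;hydroxylation:adb_residue;defluor_oh:side_chain,144.0444;230.1176
M11,5.77,C20H29N3O4,376.2231,hydroxylation:core;defluor_oh:side_chain,160.0393;246.1125;359.1965
M12,5.83,C20H28FN3O4,394.2137,hydroxylation:adb_residue;hydroxylation:side_chain,144.0444;248.1081;377.1871
M13,5.85,C20H28FN3O4,394.2137,hydroxylation:core;hydroxylation:side_chain,160.0393;264.1031;377.1871
M14,5.85,C15H19N3O2,274.1550,n_dealkylation:side_chain,144.0444;229.1335;257.1285
M15,6.02,C20H28FN3O4,394.2137,hydroxylation:adb_residue;hydroxylation:core,160.0393;248.1031;377.1871
M16,6.20,C20H25N3O4,372.1918,dehydrogenation:adb_residue;oxidation_aldehyde:adb_residue;defluor_oh:side_chain,144.0444;230.1176
M17,6.47,C20H27N3O4,374.2074,defluor_cooh:side_chain,101.0597;144.0444;244.0968;357.1809
M18,6.47,C20H28FN3O3,378.2188,hydroxylation:side_chain,144.0444;248.1081;361.1922
M19,6.54,C20H29N3O3,360.2282,defluor_oh:side_chain,144.0444;230.1176;343.2016
M20,6.60,C20H28FN3O3,378.2188,hydroxylation:side_chain,144.0444;248.1081;361.1922
M21,6.72,C20H28FN3O3,378.2188,hydroxylation:side_chain,144.0444;248.1081;361.1922
M22,6.72,C20H27N3O3,358.2125,defluor_aldehyde:side_chain,144.0444;228.1019;341.1860
M23,6.84,C20H27N3O3,358.2125,defluor_aldehyde:side_chain,144.0444;228.1019
M24,6.86,C20H26N2O4,359.1965,amide_hydrolysis:adb_residue;dehydrogenation:adb_residue;defluor_oh:side_chain,144.0444;230.1176
M25,7.01,C20H28FN3O3,378.2188,hydroxylation:core,160.0393;248.1081;361.1922
M26,7.05,C20H28FN3O3,378.2188,hydroxylation:adb_residue,144.0444;232.1132;361.1922
M27,7.07,C20H26FN3O3,376.2031,hydroxylation:adb_residue;dehydrogenation:adb_residue,144.0444;232.1132
M28,7.16,C20H27N3O3,358.2125,defluor_aldehyde:side_chain,144.0444;228.1019;341.1860
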