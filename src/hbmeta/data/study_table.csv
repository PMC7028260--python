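study_id,label,population,outcome,adjusted,stratum,cat_lower,cat_upper,cat_point,cases,total,rr,ci_lower,ci_upper,is_reference,per_unit_rr,per_unit_lo,per_unit_hi,ami_cohort,auxiliary,study_cases,study_total,cat_label
halkos,Halkos,mixed,POAF_CABG,true,,,,,,,,,,,0.89,0.8,0.98,false,false,549.0,3089.0,
matsuura,Matsuura,mixed,POAF_CABG,false,,,,,,,,,,,0.87,0.64,1.19,false,false,26.0,101.0,
tsuruta,Tsuruta,mixed,POAF_CABG,false,,,6.5,,,,1.0,,,true,1.12,0.76,1.65,false,false,36.0,305.0,
tsuruta,Tsuruta,mixed,POAF_CABG,false,,6.5,7.5,,,,0.89,0.36,2.21,false,,,,false,false,,,
tsuruta,Tsuruta,mixed,POAF_CABG,false,,7.5,,,,,1.25,0.58,2.71,false,,,,false,false,,,
kinoshita,Kinoshita,mixed,POAF_CABG,true,,3.8,5.6,,,,1.0,,,true,0.78,0.63,0.95,false,false,159.0,805.0,
kinoshita,Kinoshita,mixed,POAF_CABG,true,,6.8,11.4,,,,0.55,0.35,0.88,false,,,,false,false,,,
surer,Surer,mixed,POAF_CABG,false,,,,,,,,,,,3.92,1.92,7.99,false,false,12.0,72.0,
abbaszadeh,Abbaszadeh,mixed,POAF_CABG,true,,,,,,,,,,,1.06,0.93,1.2,false,false,109.0,708.0,
dublin,Dublin,no_known_diabetes,AF,true,,,,5.0,,,1.0,,,true,1.14,0.96,1.35,false,false,1410.0,3613.0,
dublin,Dublin,no_known_diabetes,AF,true,,,7.0,,,,1.06,0.74,1.51,false,,,,false,false,,,
dublin,Dublin,no_known_diabetes,AF,true,,7.0,8.0,,,,1.48,1.09,2.01,false,,,,false,false,,,
dublin,Dublin,no_known_diabetes,AF,true,,8.0,9.0,,,,1.46,1.02,2.08,false,,,,false,false,,,
dublin,Dublin,no_known_diabetes,AF,true,,9.0,,,,,1.96,1.22,3.14,false,,,,false,false,,,
huxley_nondm,Huxley,no_known_diabetes,AF,true,non-DM,,,,,,,,,,1.05,0.96,1.15,false,false,1311.0,13025.0,
huxley_dm,Huxley,diabetes_or_IGT,AF,true,DM,,,,,,,,,,1.13,1.07,1.2,false,false,1311.0,13025.0,
iguchi,Iguchi,no_known_diabetes,AF,true,,,,,,,,,,,1.18,1.09,1.28,false,false,1161.0,52448.0,
turgut,Turgut,diabetes_or_IGT,AF,true,,,,,,,,,,,1.87,0.747,3.014,false,false,81.0,162.0,
latini,Latini,diabetes_or_IGT,AF,true,,,,,,,,,,,1.11,0.91,1.32,false,false,613.0,8943.0,
sandhu,Sandhu,no_known_diabetes,AF,true,,,,,,,,,,,1.08,0.95,1.22,false,false,1039.0,34720.0,
sandhu_parox,Sandhu,no_known_diabetes,AF,true,paroxysmal,,4.84,,,,1.0,,,true,,,,false,true,1039.0,34720.0,
sandhu_parox,Sandhu,no_known_diabetes,AF,true,paroxysmal,4.84,5.0,,,,0.9,0.69,1.17,false,,,,false,true,,,
sandhu_parox,Sandhu,no_known_diabetes,AF,true,paroxysmal,5.0,5.19,,,,0.99,0.77,1.27,false,,,,false,true,,,
sandhu_parox,Sandhu,no_known_diabetes,AF,true,paroxysmal,5.19,,,,,0.76,0.58,1.0,false,,,,false,true,,,
sandhu_nonparox,Sandhu,no_known_diabetes,AF,true,nonparoxysmal,,4.84,,,,1.0,,,true,,,,false,true,1039.0,34720.0,
sandhu_nonparox,Sandhu,no_known_diabetes,AF,true,nonparoxysmal,4.84,5.0,,,,1.3,0.85,1.97,false,,,,false,true,,,
sandhu_nonparox,Sandhu,no_known_diabetes,AF,true,nonparoxysmal,5.0,5.19,,,,1.43,0.96,2.15,false,,,,false,true,,,
sandhu_nonparox,Sandhu,no_known_diabetes,AF,true,nonparoxysmal,5.19,,,,,1.48,0.98,2.22,false,,,,false,true,,,
blasco,Blasco,no_known_diabetes,AF,true,,,5.5,,,,1.0,,,true,3.24,2.41,4.35,true,false,12.0,601.0,
blasco,Blasco,no_known_diabetes,AF,true,,5.5,6.4,,,,1.68,0.64,4.39,false,,,,true,false,,,
blasco,Blasco,no_known_diabetes,AF,true,,6.4,,,,,29.74,10.79,81.94,false,,,,true,false,,,
dahlqvist,Dahlqvist,diabetes_or_IGT,AF,true,,,,,,,1.0,,,true,1.14,1.06,1.24,false,false,1283.0,216852.0,Control
dahlqvist,Dahlqvist,diabetes_or_IGT,AF,true,,,6.9,,,,1.03,0.84,1.27,false,,,,false,false,,,
dahlqvist,Dahlqvist,diabetes_or_IGT,AF,true,,7.0,7.8,,,,1.11,0.97,1.28,false,,,,false,false,,,
dahlqvist,Dahlqvist,diabetes_or_IGT,AF,true,,7.8,8.7,,,,1.28,1.12,1.47,false,,,,false,false,,,
dahlqvist,Dahlqvist,diabetes_or_IGT,AF,true,,8.8,9.6,,,,1.4,1.15,1.69,false,,,,false,false,,,
dahlqvist,Dahlqvist,diabetes_or_IGT,AF,true,,9.7,,,,,2.32,1.8,2.99,false,,,,false,false,,,
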