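# Study-arm summary statistics (mean, SD, n) per endpoint and timepoint,
# transcribed from the published summary tables.
# measure: baseline = pre-operative level; change = change from baseline.
# subgroup: all = whole cohort; chl_mhl = conductive/mixed hearing loss subgroup.
study_id,endpoint,timepoint_months,measure,subgroup,n,mean,sd,source
mylanus,pta4,0,baseline,all,51,53.90,11.60,"audiological outcomes table, PTA4 pre-operative"
briggs,pta4,0,baseline,all,29,53.60,11.30,"audiological outcomes table, PTA4 pre-operative"
den_besten,pta4,0,baseline,all,54,51.94,10.46,"audiological outcomes table, PTA4 pre-operative"
mylanus,pta4,6,change,all,49,27.90,9.10,"audiological outcomes table, PTA4 change at 6 months"
briggs,pta4,6,change,all,28,28.40,9.60,"audiological outcomes table, PTA4 change at 6 months"
den_besten,pta4,6,change,all,54,21.02,10.41,"audiological outcomes table, PTA4 change at 6 months"
mylanus,speech_quiet,0,baseline,all,51,25.50,25.40,"audiological outcomes table, speech in quiet pre-operative"
briggs,speech_quiet,0,baseline,all,29,37.80,30.30,"audiological outcomes table, speech in quiet pre-operative"
den_besten,speech_quiet,0,baseline,all,54,46.76,32.62,"audiological outcomes table, speech in quiet pre-operative"
mylanus,speech_quiet,6,change,all,48,61.50,27.70,"audiological outcomes table, speech in quiet change at 6 months"
briggs,speech_quiet,6,change,all,28,54.00,29.80,"audiological outcomes table, speech in quiet change at 6 months"
den_besten,speech_quiet,6,change,all,54,43.44,31.47,"audiological outcomes table, speech in quiet change at 6 months"
mylanus,speech_noise,0,baseline,all,51,4.98,7.76,"audiological outcomes table, speech in noise pre-operative"
den_besten,speech_noise,0,baseline,all,36,8.57,6.26,"audiological outcomes table, speech in noise pre-operative"
mylanus,speech_noise,6,change,all,48,13.70,8.10,"audiological outcomes table, speech in noise change at 6 months"
den_besten,speech_noise,6,change,all,36,4.26,5.66,"audiological outcomes table, speech in noise change at 6 months"
mylanus,hui3,0,baseline,all,46,0.65,0.22,"health utility table, pre-operative, all patients"
briggs,hui3,0,baseline,all,29,0.69,0.23,"health utility table, pre-operative, all patients"
den_besten,hui3,0,baseline,all,52,0.66,0.24,"health utility table, pre-operative, all patients"
mylanus,hui3,3,change,all,42,0.08,0.23,"health utility table, change at 3 months, all patients"
briggs,hui3,3,change,all,27,0.10,0.17,"health utility table, change at 3 months, all patients"
briggs,hui3,6,change,all,27,0.09,0.17,"health utility table, change at 6 months, all patients"
den_besten,hui3,6,change,all,47,0.06,0.25,"health utility table, change at 6 months, all patients"
mylanus,hui3,0,baseline,chl_mhl,34,0.61,0.22,"health utility table, pre-operative, CHL/MHL"
briggs,hui3,0,baseline,chl_mhl,24,0.65,0.22,"health utility table, pre-operative, CHL/MHL"
den_besten,hui3,0,baseline,chl_mhl,37,0.67,0.21,"health utility table, pre-operative, CHL/MHL"
mylanus,hui3,3,change,chl_mhl,30,0.10,0.24,"health utility table, change at 3 months, CHL/MHL"
briggs,hui3,3,change,chl_mhl,23,0.12,0.17,"health utility table, change at 3 months, CHL/MHL"
briggs,hui3,6,change,chl_mhl,23,0.12,0.15,"health utility table, change at 6 months, CHL/MHL"
den_besten,hui3,6,change,chl_mhl,34,0.06,0.23,"health utility table, change at 6 months, CHL/MHL"
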