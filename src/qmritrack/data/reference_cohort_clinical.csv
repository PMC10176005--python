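subject_id,edss_t0,edss_mid,new_lesion_mid,relapse_mid,neda_mid,edss_t1,new_lesion_end,relapse_end,neda_end,interval_months,score
sub-001,2,2,none,none,YES,2,none,none,YES,30,1
sub-002,1.5,1.5,none,none,YES,1.5,none,none,YES,27,1
sub-003,2,2,none,none,YES,2,none,none,YES,27,1
sub-004,3,3,none,none,YES,3.5,none,none,YES,25,1
sub-005,1,1,none,none,YES,1,none,none,YES,24,1
sub-006,1.5,1.5,none,none,YES,1.5,none,none,YES,24,1
sub-007,2,2,none,none,YES,2,none,none,YES,22,1
sub-008,3.5,4.5,none,NA,NO,5,none,NA,NO,51,0
sub-009,2,2.5,none,none,YES,2.5,none,none,YES,57,1
sub-010,6,6,yes,NA,NO,6.5,none,none,NO,14,0
sub-011,6,6,none,NA,YES,6.5,none,NA,NO,14,1
sub-012,1,1.5,none,none,YES,1.5,none,none,YES,55,1
sub-013,5.5,6,none,NA,NO,6.5,none,NA,NO,60,0
sub-014,2.5,3.5,yes,yes,NO,3,none,none,YES,57,1
sub-015,4,4.5,none,NA,NO,5,none,NA,NO,51,0
sub-016,5,4.5,yes,NA,NO,4.5,none,NA,YES,61,1
sub-017,2,3,yes,yes,NO,3,yes,yes,NO,56,0
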