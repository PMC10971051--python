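# Device/procedure-related event counts with person-months of follow-up,
# transcribed from the published adverse-event summaries.
arm,event_type,events,patients,exposure_months,source
osia,soft_tissue_complication,3,80,786,"3 soft-tissue events in 80 patients over 786 exposure-months"
osia,reoperation,1,80,786,"1 explantation in 80 patients over 786 exposure-months"
baha,soft_tissue_complication,4,54,324,"4 soft-tissue events in 54 patients over 324 exposure-months (6-month window)"
baha,reoperation,4,54,1296,"4 reoperations in 54 patients over 1296 exposure-months (24-month window)"
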