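# Baseline cohort demographics transcribed from the published
# patient-characteristics table.
study_id,arm,n,age_mean,age_sd,male_n
mylanus,osia,51,47.4,14.7,27
briggs,osia,29,46.7,19.7,13
den_besten,baha,54,42.1,13.6,21
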