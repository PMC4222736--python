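subject_id,heart_rate_bpm,brachial_sys_mmHg,brachial_dia_mmHg,aortic_sys_mmHg,aortic_dia_mmHg,ventricular_sys_mmHg,doppler_co_ml_min,numerical_co_ml_min,ejection_time_s
subject-01,98,,,,68,152,11356,10916.97,
subject-01,106,,,,65,158,12651,12478.27,
subject-01,114,,,,63,165,14051,14031.32,
subject-01,125,,,,63,169,15298,15487.93,
subject-01,136,,,,64,174,16172,16686.83,
subject-01,147,,,,65,178,17225,18012.27,
subject-01,153,,,,66,180,17330,18445.6,
subject-01,159,,,,67,182,17941,18844.08,
subject-01,169,,,,68,186,18849,19817.15,
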