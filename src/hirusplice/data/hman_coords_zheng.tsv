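# seq_id: chromosome_3
gene	start	end	orientation
Hman_DV1	12431399	12434976	fw
Hman_DV2	12437478	12440006	fw
Hman_DV3	12441249	12444510	fw
Hman_DV4	12445166	12446038	fw
Hman_DV5	12447043	12450617	fw
Hman_HV1	12587203	12587806	re_co
Hman_HV2	12583089	12583742	re_co
Hman_HV3	12580970	12581635	re_co
Hman_HV4	12575511	12576174	re_co
Hman_TH	12571738	12572909	re_co
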