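# seq_id: chromosome_4
gene	start	end	orientation
Hman_DV1	12102877	12106430	fw
Hman_DV2	12108608	12111161	fw
Hman_DV3	12112407	12115657	fw
Hman_DV4	12116319	12117203	fw
Hman_DV5	12118197	12120025	fw
Hman_HV1	12249296	12249899	re_co
Hman_HV2	12245322	12245958	re_co
Hman_HV3	12243197	12243865	re_co
Hman_HV4	12240038	12240688	re_co
Hman_TH	12236266	12237439	re_co
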