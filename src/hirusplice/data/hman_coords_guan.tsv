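# seq_id: contig00065
gene	start	end	orientation
Hman_DV1	1441956	1445508	re_co
Hman_DV2	1437246	1439788	re_co
Hman_DV3	1432730	1436010	re_co
Hman_DV4	1431197	1432077	re_co
Hman_DV5	1426608	1430176	re_co
Hman_HV1	1283961	1284564	fw
Hman_HV2	1287886	1288539	fw
Hman_HV3	1289984	1290638	fw
Hman_HV4	1297158	1297813	fw
Hman_TH	1300423	1301910	fw
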