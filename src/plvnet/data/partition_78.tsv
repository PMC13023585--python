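region_label	network_label
LH_SMN_1	SMN
LH_SMN_2	SMN
LH_SMN_3	SMN
LH_SMN_4	SMN
LH_SMN_5	SMN
LH_SMN_6	SMN
LH_SMN_7	SMN
RH_SMN_1	SMN
RH_SMN_2	SMN
RH_SMN_3	SMN
RH_SMN_4	SMN
RH_SMN_5	SMN
RH_SMN_6	SMN
RH_SMN_7	SMN
LH_DAN_1	DAN
LH_DAN_2	DAN
LH_DAN_3	DAN
LH_DAN_4	DAN
LH_DAN_5	DAN
LH_DAN_6	DAN
LH_DAN_7	DAN
RH_DAN_1	DAN
RH_DAN_2	DAN
RH_DAN_3	DAN
RH_DAN_4	DAN
RH_DAN_5	DAN
RH_DAN_6	DAN
RH_DAN_7	DAN
RH_DAN_8	DAN
LH_SN_1	SN
LH_SN_2	SN
LH_SN_3	SN
LH_SN_4	SN
LH_SN_5	SN
LH_SN_6	SN
RH_SN_1	SN
RH_SN_2	SN
RH_SN_3	SN
RH_SN_4	SN
RH_SN_5	SN
RH_SN_6	SN
LH_CEN_1	CEN
LH_CEN_2	CEN
LH_CEN_3	CEN
LH_CEN_4	CEN
LH_CEN_5	CEN
LH_CEN_6	CEN
RH_CEN_1	CEN
RH_CEN_2	CEN
RH_CEN_3	CEN
RH_CEN_4	CEN
RH_CEN_5	CEN
RH_CEN_6	CEN
RH_CEN_7	CEN
LH_DMN_1	DMN
LH_DMN_2	DMN
LH_DMN_3	DMN
LH_DMN_4	DMN
LH_DMN_5	DMN
LH_DMN_6	DMN
LH_DMN_7	DMN
LH_DMN_8	DMN
LH_DMN_9	DMN
LH_DMN_10	DMN
LH_DMN_11	DMN
LH_DMN_12	DMN
RH_DMN_1	DMN
RH_DMN_2	DMN
RH_DMN_3	DMN
RH_DMN_4	DMN
RH_DMN_5	DMN
RH_DMN_6	DMN
RH_DMN_7	DMN
RH_DMN_8	DMN
RH_DMN_9	DMN
RH_DMN_10	DMN
RH_DMN_11	DMN
RH_DMN_12	DMN
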