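channel	hemisphere
ch1	left_PFC
ch2	left_PFC
ch3	left_PFC
ch4	left_PFC
ch5	left_PFC
ch6	left_PFC
ch7	left_PFC
ch8	left_PFC
ch9	left_PFC
ch10	left_PFC
ch11	left_PFC
ch12	left_PFC
ch13	left_PFC
ch14	left_PFC
ch15	left_PFC
ch16	left_PFC
ch22	right_PFC
ch23	right_PFC
ch24	right_PFC
ch25	right_PFC
ch26	right_PFC
ch27	right_PFC
ch28	right_PFC
ch29	right_PFC
ch30	right_PFC
ch31	right_PFC
ch32	right_PFC
ch33	right_PFC
ch34	right_PFC
ch35	right_PFC
ch36	right_PFC
ch37	right_PFC
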