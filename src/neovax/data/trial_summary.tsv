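patient_id	n_epitopes	immune_response	recurrence
BRC06	20	Y	N
BRC08	14	Y	N
BRC10	10	Y	N
BRC16	7	N	Y
BRC18	10	Y	N
BRC19	11	Y	N
BRC45	8	Y	N
BRC46	20	Y	N
BRC56	10	Y	N
BRC58	17	Y	N
BRC64	10	Y	N
BRC65	4	Y	N
BRC73	10	Y	N
BRC77	6	N	Y
BRC78	7	Y	N
BRC80	4	N	N
BRC93	10	N	N
BRC98	20	N	N
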