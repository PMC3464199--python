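tetrad_id	grain	red	yellow	cyan
T01	1	1	1	1
T01	2	0	1	1
T01	3	1	1	0
T01	4	0	0	0
T02	1	0	1	1
T02	2	1	1	1
T02	3	1	1	0
T02	4	0	0	0
T03	1	0	0	0
T03	2	1	1	0
T03	3	0	1	1
T03	4	1	1	1
T04	1	1	1	1
T04	2	1	1	0
T04	3	0	1	1
T04	4	0	0	0
T05	1	1	1	0
T05	2	1	1	1
T05	3	0	0	0
T05	4	0	1	1
T06	1	1	1	1
T06	2	0	1	1
T06	3	0	0	0
T06	4	1	1	0
T07	1	0	1	1
T07	2	1	1	0
T07	3	1	1	1
T07	4	0	0	0
T08	1	0	0	0
T08	2	1	1	1
T08	3	0	1	1
T08	4	1	1	0
T09	1	1	1	0
T09	2	0	0	0
T09	3	1	1	1
T09	4	0	1	1
T10	1	1	1	1
T10	2	0	0	0
T10	3	1	1	0
T10	4	0	1	1
T11	1	0	1	1
T11	2	0	0	0
T11	3	1	1	0
T11	4	1	1	1
T12	1	1	1	1
T12	2	1	1	1
T12	3	0	1	0
T12	4	0	0	0
T13	1	1	1	1
T13	2	1	1	1
T13	3	0	1	NA
T13	4	0	0	0
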