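case_id	n_diagnostic	n_diag_retained_eyeg2p	n_retained_eyeg2p	n_diag_retained_updated_tiering	n_retained_updated_tiering
1	2	2	8	2	5
2	1	1	8	1	6
3	2	2	11	2	7
4	2	2	4	2	7
5	2	2	7	2	4
6	1	1	9	1	6
7	1	1	3	1	8
8	2	2	7	1	3
9	2	2	10	1	5
10	2	2	9	2	4
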