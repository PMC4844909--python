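# Reported user/NLP/reference agreement counts for the preannotation-assisted
# scenario of the feasibility study this package models.  151 reference PDDI
# mentions; 93 NLP mentions absent from the reference standard.  The first
# four columns partition the reference mentions; nlp_fp_user_tn plus
# nlp_fp_user_fp partition the NLP false positives; nlp_tn_user_fp is the
# count of user mentions matching neither (reported as a bare count).
participant	nlp_fn_user_fn	nlp_fn_user_tp	nlp_tp_user_fn	nlp_tp_user_tp	nlp_tn_user_fp	nlp_fp_user_tn	nlp_fp_user_fp
Expert	59	50	23	19	25	93	0
Nonexpert 1	46	63	11	31	16	88	5
Nonexpert 2	43	66	11	31	37	86	7
Nonexpert 3	49	60	13	29	24	88	5
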