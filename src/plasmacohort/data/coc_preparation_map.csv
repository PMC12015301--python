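# Curated default mapping of contraceptive preparation codes to the estrogen
# class of the preparation (EE = ethinylestradiol-containing combined oral
# contraceptive, BE = bioidentical estrogen, P4 = progestogen-only,
# non_oral = non-oral route, excluded from the subtype comparison).
# ATC codes alone under-determine the estrogen type of some fixed
# combinations; edit or replace this table for a concrete formulary.
preparation_code,estrogen_class
G03AA05,EE
G03AA07,EE
G03AA09,EE
G03AA10,EE
G03AA11,EE
G03AA12,EE
G03AA13,EE
G03AB03,EE
G03AB04,EE
G03AB05,EE
G03AA14,BE
G03AB08,BE
G03AC01,P4
G03AC02,P4
G03AC03,P4
G03AC09,P4
G03AC10,P4
G03AC08,non_oral
G02BA03,non_oral
G02BB01,non_oral
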