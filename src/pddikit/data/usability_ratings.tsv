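# Reported ease-of-use ratings from the annotation feasibility study this
# package models (5-point scale, 1 = very difficult, 5 = very easy), one row
# per participant x scenario for the three scenarios with questionnaires.
participant	scenario	rating
Expert	1	2
Expert	2	4
Expert	3	2
Nonexpert 1	1	4
Nonexpert 1	2	5
Nonexpert 1	3	2
Nonexpert 2	1	4
Nonexpert 2	2	5
Nonexpert 2	3	2
Nonexpert 3	1	3
Nonexpert 3	2	3
Nonexpert 3	3	2
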