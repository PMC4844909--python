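# Self-reported task completion time categories from the annotation
# feasibility study this package models, per participant x scenario.
participant	scenario	category
Expert	1	<1h
Expert	2	<1h
Expert	3	<1h
Nonexpert 1	1	<1h
Nonexpert 1	2	<1h
Nonexpert 1	3	<1h
Nonexpert 2	1	1-3h
Nonexpert 2	2	<1h
Nonexpert 2	3	<1h
Nonexpert 3	1	3-5h
Nonexpert 3	2	3-5h
Nonexpert 3	3	>5h
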