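phrase	note
no effect	explicit denial
did not	negated past-tense claim
does not	negated present-tense claim
do not	negated present-tense claim
was not	negated passive
were not	negated passive
no significant	denial of a significant change
not significantly	denial of a significant change
not altered	denial of alteration
no clinically significant	denial of clinical relevance
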