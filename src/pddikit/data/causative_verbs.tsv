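stem	note
increase	raises exposure of the object drug
decrease	lowers exposure
reduce	lowers exposure
inhibit	enzyme/transporter inhibition
induce	enzyme induction
elevate	raises exposure
prolong	lengthens half-life
alter	unspecified change
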