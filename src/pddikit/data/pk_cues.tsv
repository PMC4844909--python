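stem	note
auc	area under the concentration-time curve
cmax	peak plasma concentration
clearance	systemic or renal clearance
concentration	plasma/serum concentration
half-life	elimination half-life
pharmacokinetic	includes "pharmacokinetics"
inhibit	inhibits/inhibited/inhibition
induce	induces/induced/induction
increase	increases/increased
decrease	decreases/decreased
reduce	reduces/reduced/reduction
elevate	elevates/elevated
prolong	prolongs/prolonged
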