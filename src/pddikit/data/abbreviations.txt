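# One abbreviation per line (with trailing period); matching is case-insensitive.
e.g.
i.e.
i.v.
i.m.
p.o.
b.i.d.
t.i.d.
q.d.
dr.
mr.
mrs.
ms.
vs.
etc.
approx.
fig.
al.
et al.
no.
resp.
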