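# Abbreviations after which the sentence splitter must not break.
# One entry per line; comparison is case-insensitive on the final token.
e.g.
i.e.
i.v.
i.m.
s.c.
p.o.
b.i.d.
t.i.d.
q.d.
vs.
al.
Fig.
Figs.
Tab.
Ref.
Dr.
Prof.
approx.
ca.
St.
no.
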