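# Abbreviations that end in a period but do not end a sentence.
# One entry per line; matched case-insensitively against the token
# preceding a candidate sentence boundary.
z.B.
z.b.
d.h.
u.a.
bzw.
usw.
etc.
ca.
evtl.
ggf.
inkl.
vgl.
Nr.
Dr.
Prof.
Mio.
bspw.
sog.
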