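# Default German filler lexicon, one lowercase token per line.
# Edit freely; tokens are removed as whole words, case-insensitively.
ähm
äh
öhm
öh
hm
hmm
mhm
halt
quasi
sozusagen
naja
tja
achso
joa
ähhm
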