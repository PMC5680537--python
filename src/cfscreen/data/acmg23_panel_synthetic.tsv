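# Synthetic stand-in for the 23-mutation pan-ethnic ACMG carrier-testing panel.
# Mutation ids are the panel's well-known CFTR variants; the per-mutation
# population shares are illustrative (the model only consumes their sum,
# the panel coverage a = 0.834).
mutation_id	population_share
F508del	0.6960
G542X	0.0230
G551D	0.0210
W1282X	0.0120
N1303K	0.0120
R553X	0.0090
621+1G>T	0.0080
1717-1G>A	0.0070
3849+10kbC>T	0.0060
3120+1G>A	0.0060
2789+5G>A	0.0040
R117H	0.0040
I507del	0.0030
A455E	0.0030
G85E	0.0030
R560T	0.0020
R334W	0.0020
R347P	0.0020
711+1G>T	0.0020
1898+1G>A	0.0020
2184delA	0.0020
3659delC	0.0040
1078delT	0.0010
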