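# Oligomeric-state keywords, one per line: keyword <tab> subunit count.
# Matching is case-insensitive with morphological expansion (plural "-s",
# adjectival "-ic", and "homo-"/"hetero-" prefixes), so "homodimeric"
# matches the "dimer" entry.  Edit or replace via --oligo-kw.
monomer	1
dimer	2
trimer	3
tetramer	4
pentamer	5
hexamer	6
heptamer	7
octamer	8
nonamer	9
decamer	10
undecamer	11
dodecamer	12
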