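# Synthetic Shine-Dalgarno (ribosome binding site) collection seeded on
# the anti-16S-rRNA-tail consensus AGGAGG; assembled for this package,
# not derived from any curated database.
AGGAGG
AGGAGG
AGGAGG
AGGAGG
AGGAGG
AGGAGA
AGGTGG
AGAAGG
GGGAGG
AGGAGT
TGGAGG
AGGGGG
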