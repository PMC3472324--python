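# Synthetic sigma70 -35 box site collection, Gram-negative flavour.
# Assembled for this package around the canonical TTGACA consensus with
# the column variability typical of compiled E. coli-like promoter
# alignments; not derived from any curated database.
TTGACA
TTGACA
TTGACA
TTGACA
TTGACT
TTGACG
TTCACA
GTGACA
TTGAAA
TTTACA
TTGATA
CTGACA
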