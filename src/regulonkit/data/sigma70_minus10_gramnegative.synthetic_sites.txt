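# Synthetic sigma70 -10 (Pribnow) box site collection, Gram-negative
# flavour.  Assembled for this package around the canonical TATAAT
# consensus; not derived from any curated database.
TATAAT
TATAAT
TATAAT
TATAAT
TACAAT
TATACT
TATAAT
GATAAT
TATGAT
TAAAAT
CATAAT
TATCAT
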