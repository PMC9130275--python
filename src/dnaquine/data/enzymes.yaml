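# Restriction enzyme rules.
# recognition: IUPAC text; offsets: cut positions relative to the recognition
# start on the strand carrying the recognition text (top_offset severs the
# top strand, bottom_offset the bottom strand, both in top coordinates).
# Type IIS enzymes cut outside the recognition site (offsets > its length).
EcoRI:   {recognition: GAATTC, top_offset: 1, bottom_offset: 5}
BamHI:   {recognition: GGATCC, top_offset: 1, bottom_offset: 5}
HindIII: {recognition: AAGCTT, top_offset: 1, bottom_offset: 5}
XhoI:    {recognition: CTCGAG, top_offset: 1, bottom_offset: 5}
NdeI:    {recognition: CATATG, top_offset: 2, bottom_offset: 4}
EcoRV:   {recognition: GATATC, top_offset: 3, bottom_offset: 3}
SmaI:    {recognition: CCCGGG, top_offset: 3, bottom_offset: 3}
PstI:    {recognition: CTGCAG, top_offset: 5, bottom_offset: 1}
BsaI:    {recognition: GGTCTC, top_offset: 7, bottom_offset: 11}
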