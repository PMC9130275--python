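# Site-specific recombinase target sites.
#
# Tyrosine-family sites (regenerated by the reaction) follow the
# arm/spacer/inverted-arm layout; the asymmetric spacer gives each site its
# orientation.  loxP, FRT and F3 are the canonical published 34-bp texts.
# vox (Vika) and B3RT here are SYNTHETIC stand-ins with the same layout, as
# are the attB/attP/attL/attR texts of the serine integrases (built as
# B5+core+B3 / P5+core+P3, recombining to B5+core+P3 / P5+core+B3): the
# stand-in circuits in the fixtures module only require the sites to be
# mutually non-matching and orientation-asymmetric, not biologically exact.
Cre:
  family: loxP
  mechanism: tyrosine
  site: ATAACTTCGTATAATGTATGCTATACGAAGTTAT
FLP:
  family: FRT
  mechanism: tyrosine
  site: GAAGTTCCTATTCTCTAGAAAGTATAGGAACTTC
FLP_F3:
  family: F3
  mechanism: tyrosine
  site: GAAGTTCCTATTCTTCAAATAGTATAGGAACTTC
Vika:
  family: vox
  mechanism: tyrosine
  site: TACGCATGGACCTGACTTCGAACAGGTCCATGCGTA   # synthetic
B3:
  family: B3RT
  mechanism: tyrosine
  site: CGGATAACCTGTCATGAACTTCTGACAGGTTATCCG   # synthetic
PhiC31:
  family: attPhiC31
  mechanism: serine_integrase
  attB: CCGCGGTGCGGGTGTTGAGTTCTCTCAGTT         # synthetic
  attP: GTAGTGCCCCAACTTTGGGGTAACCTTTGA         # synthetic
  attL: CCGCGGTGCGGGTGTTGGGGTAACCTTTGA         # synthetic
  attR: GTAGTGCCCCAACTTTGAGTTCTCTCAGTT         # synthetic
Bxb1:
  family: attBxb1
  mechanism: serine_integrase
  attB: GGCTTGTCGACGACTTGATGGTGTCGTAGA         # synthetic
  attP: GTCGTGGTTTGTCTTTCGACCTGTAGTCAA         # synthetic
  attL: GGCTTGTCGACGACTTCGACCTGTAGTCAA         # synthetic
  attR: GTCGTGGTTTGTCTTTGATGGTGTCGTAGA         # synthetic
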