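# Curated germline repeat-family signatures for Blepharisma stoltei.
# tir / tsd_list / BogoMITE consensus_len and the BstTc1 microsatellite unit
# are the curated family signatures; consensus_len for the autonomous
# families Bogo and BstTc1 are nominal package defaults used by the
# synthetic-data generator, not measured element lengths.
name	tir	tsd_list	consensus_len	classification	microsat_unit
Bogo	CTCCCCCCCCCCCTCCGTGAGCGAACAAAA	TAA,TTA	2400	DNA/TcMar-Pogo
BogoMITE	CTCCCCCCCCCCCTCCGTGAGCGAACAAAA	TAA,TTA	389	DNA/TcMar-Pogo-MITE
BstTc1	GTACCCCCCCCCTCGTTTGTCGCATTTTCTAGTTTTTT	TATA	1600	DNA/TcMar-Tc1	GGGAAGGACT
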