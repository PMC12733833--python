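# Bundled restriction-enzyme table.
# Recognition motifs are IUPAC strings; cut positions use REBASE-style
# notation (caret inside the motif, or trailing (t/b) for outside cutters).
# Exact cut offsets are drawn from the standard enzyme reference (REBASE),
# not from any single application study, which typically prints motifs and
# fragment sizes only.
name	recognition	comment
Cac8I	GCN^NGC	blunt cutter, degenerate core
BsmAI	GTCTC(1/5)	type IIS outside cutter
BstEII	G^GTNACC	5' overhang, degenerate core
MwoI	GCNNNNN^NNGC	3' overhang, highly degenerate
SspI	AAT^ATT	blunt cutter
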