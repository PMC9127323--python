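# Tolerated non-canonical residue substitutions: the modified residue is
# mapped onto its canonical parent by deleting the listed atoms, leaving all
# retained coordinates untouched. Entries where the parent geometry would
# require rebuilding coordinates are deliberately absent: such templates are
# rejected instead.
# code	canonical	atoms_to_delete
SEP	SER	P,O1P,O2P,O3P
TPO	THR	P,O1P,O2P,O3P
PTR	TYR	P,O1P,O2P,O3P
CSO	CYS	OD
ALY	LYS	OH,CH3,CH
M3L	LYS	CM1,CM2,CM3
MLY	LYS	CH1,CH2
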