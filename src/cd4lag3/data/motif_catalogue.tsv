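name	pattern	note
cd4_clasp	Cx[CH]	CD4 cytoplasmic-tail zinc-clasp motif for LCK binding; H can replace C in tetrahedral Zn coordination
cd4_clasp_cxf	CxF	sturgeon CD4-2f variant in which the second clasp cysteine is replaced by phenylalanine
lck_clasp_partner	CxxC	LCK-side clasp partner; also the neoteleost CD4-2 hinge/linker motif (possible homodimerization)
itim_like	[FY]xxL[DE]	LAG-3 inhibitory tail motif resembling an ITIM
fxxl_core	FxxL	four-residue core of the inhibitory motif, reported separately from the acidic fifth position
lag3_fpal	FPAL[DE]	frequent concrete realization of the LAG-3 inhibitory motif
itim_canonical	[IVL]xYxx[LV]	canonical ITIM consensus; found in some teleost LAG-3 tails
yxxm	YxxM	SH2-docking variant seen in zebrafish/channel catfish LAG-3
cd41_cterm	P[KQ]P[KR][AG]FY[HKR]	conserved CD4-1 C-terminal tail motif of ray-finned fish
wxc	WxC	unusual tryptophan-x-cysteine signature in beta-strand F of Ig-like C2 domains D2/D4
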