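# Haplogroup-defining SNP catalog for external-mode background scans.
# Coordinates are rCRS (NC_012920) positions on chrM; this file is only
# meaningful when aligning against a real human reference in external mode.
# Rows whose printed allele equals the rCRS base (haplogroup-diagnostic
# states the reference already carries) are skipped by the loader.
contig	pos	ref	alt	label
chrM	1736	A	G	A
chrM	235	A	G	A
chrM	4824	A	G	A
chrM	663	A	G	A
chrM	4248	T	C	A
chrM	16290	C	T	A
chrM	8794	C	T	A
chrM	16319	G	A	A
chrM	152	T	C	A
chrM	2706	A	A	H
chrM	7028	C	C	H
chrM	3010	G	A	H
chrM	9221	A	G	L2
chrM	150	C	T	L2
chrM	13590	G	A	L2
chrM	16390	G	A	L2
chrM	8206	G	A	L2
chrM	10115	T	C	L2
chrM	146	T	C	L2
chrM	152	T	C	L2
chrM	16311	T	C	L2
chrM	2416	T	C	L2
chrM	489	T	C	M
chrM	10400	C	T	M
chrM	14873	T	C	M
chrM	15043	G	A	M
chrM	12372	G	A	U
chrM	9332	C	T	loss
chrM	10978	A	G	L6
chrM	11914	G	A	C
chrM	709	G	A	L6/G/N2/T
chrM	8392	G	A	Y
chrM	6221	T	C	X
chrM	1888	G	A	T
chrM	13368	G	A	T
chrM	8206	G	A	L2
chrM	14569	G	A	M12'G
chrM	5843	A	G	Q
chrM	8860	A	G	non-H2a2a1
chrM	4759	A	G	non-H2a2a1
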