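##fileformat=VCFv4.2
##source=pedibd
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=EFF,Number=1,Type=String,Description="Effect class">
##INFO=<ID=AF_PANEL1,Number=1,Type=Float,Description="Alt AF, reference panel 1">
##INFO=<ID=AF_PANEL2,Number=1,Type=Float,Description="Alt AF, reference panel 2">
##INFO=<ID=AF_PANEL3,Number=1,Type=Float,Description="Alt AF, reference panel 3">
##INFO=<ID=EVS_AF,Number=1,Type=Float,Description="External exome cohort AF">
##INFO=<ID=KG,Number=0,Type=Flag,Description="Present in thousand-genomes catalog">
##INFO=<ID=DBSNP,Number=0,Type=Flag,Description="Known dbSNP site">
##INFO=<ID=AC_CTRL,Number=1,Type=Integer,Description="Control alt allele count">
##INFO=<ID=AN_CTRL,Number=1,Type=Integer,Description="Control called chromosomes">
##INFO=<ID=VQSLOD,Number=1,Type=Float,Description="Variant quality log-odds">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##contig=<ID=1>
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	c1	c2	gf	gm	p1	p2	sp1	sp2
1	1000000	.	C	T	.	PASS	GENE=G1X0009;EFF=missense;AF_PANEL1=0;AF_PANEL2=0;AF_PANEL3=0;AC_CTRL=0;AN_CTRL=604;VQSLOD=8	GT:DP	0/1:50	0/1:50	0/1:50	0/0:50	0/1:50	0/1:50	0/0:50	0/0:50
1	1100000	.	C	T	.	PASS	GENE=G1X0010;EFF=missense;AF_PANEL1=0.03;AF_PANEL2=0.03;AF_PANEL3=0.03;EVS_AF=0.01;DBSNP;AC_CTRL=15;AN_CTRL=612;VQSLOD=8	GT:DP	0/1:50	0/1:50	0/1:50	0/0:50	0/1:50	0/1:50	0/0:50	0/0:50
1	1200000	.	C	T	.	PASS	GENE=G1X0011;EFF=missense;AF_PANEL1=0.049;AF_PANEL2=0.049;AF_PANEL3=0.049;DBSNP;AC_CTRL=0;AN_CTRL=604;VQSLOD=8	GT:DP	0/1:4	0/1:4	0/1:50	0/0:50	0/1:50	0/1:50	0/0:50	0/0:50
1	1300000	.	C	T	.	PASS	GENE=G1X0012;EFF=splice_site;AF_PANEL1=0;AF_PANEL2=0;AF_PANEL3=0;AC_CTRL=0;AN_CTRL=604;VQSLOD=8	GT:DP	0/1:50	0/1:50	0/1:50	0/0:50	0/1:50	0/1:50	0/0:50	0/0:50
1	1310000	.	C	T	.	PASS	GENE=G1X0013;EFF=missense;AF_PANEL1=0;AF_PANEL2=0;AF_PANEL3=0;AC_CTRL=0;AN_CTRL=604;VQSLOD=0	GT:DP	0/1:50	0/1:50	0/1:50	0/0:50	0/1:50	0/1:50	0/0:50	0/0:50
1	1320000	.	C	T	.	PASS	GENE=G1X0013;EFF=missense;AF_PANEL1=0;AF_PANEL2=0;AF_PANEL3=0;AC_CTRL=0;AN_CTRL=604;VQSLOD=-3	GT:DP	0/1:50	0/1:50	0/1:50	0/0:50	0/1:50	0/1:50	0/0:50	0/0:50
1	1330000	.	C	T	.	PASS	GENE=G1X0013;EFF=missense;AF_PANEL1=0;AF_PANEL2=0;AF_PANEL3=0;AC_CTRL=0;AN_CTRL=604;VQSLOD=8	GT:DP	0/1:3	0/1:50	0/1:50	0/0:50	0/1:50	0/1:50	0/0:50	0/0:50
1	1340000	.	C	T	.	PASS	GENE=G1X0013;EFF=missense;AF_PANEL1=0;AF_PANEL2=0;AF_PANEL3=0;AC_CTRL=0;AN_CTRL=604;VQSLOD=8	GT:DP	0/1:3	0/1:3	0/1:3	0/0:3	0/1:3	0/1:3	0/0:3	0/0:3
1	1350000	.	C	T	.	PASS	GENE=G1X0013;EFF=missense;AF_PANEL1=0.051;AF_PANEL2=0.051;AF_PANEL3=0.051;DBSNP;AC_CTRL=0;AN_CTRL=604;VQSLOD=8	GT:DP	0/1:50	0/1:50	0/1:50	0/0:50	0/1:50	0/1:50	0/0:50	0/0:50
1	1360000	.	C	T	.	PASS	GENE=G1X0013;EFF=missense;AF_PANEL1=0;AF_PANEL2=0;AF_PANEL3=0;EVS_AF=0.2;DBSNP;AC_CTRL=0;AN_CTRL=604;VQSLOD=8	GT:DP	0/1:50	0/1:50	0/1:50	0/0:50	0/1:50	0/1:50	0/0:50	0/0:50
1	1370000	.	C	T	.	PASS	GENE=G1X0013;EFF=missense;AF_PANEL1=0;AF_PANEL2=0;AF_PANEL3=0;DBSNP;AC_CTRL=40;AN_CTRL=604;VQSLOD=8	GT:DP	0/1:50	0/1:50	0/1:50	0/0:50	0/1:50	0/1:50	0/0:50	0/0:50
1	1380000	.	C	T	.	PASS	GENE=G1X0013;EFF=missense;AF_PANEL1=0.3;AF_PANEL2=0.3;AF_PANEL3=0.3;EVS_AF=0.3;KG;DBSNP;AC_CTRL=0;AN_CTRL=604;VQSLOD=8	GT:DP	0/1:50	0/1:50	0/1:50	0/0:50	0/1:50	0/1:50	0/0:50	0/0:50
1	1390000	.	C	T	.	PASS	GENE=G1X0013;EFF=synonymous;AF_PANEL1=0;AF_PANEL2=0;AF_PANEL3=0;AC_CTRL=0;AN_CTRL=604;VQSLOD=8	GT:DP	0/1:50	0/1:50	0/1:50	0/0:50	0/1:50	0/1:50	0/0:50	0/0:50
1	1400000	.	C	T	.	PASS	GENE=G1X0013;EFF=intronic;AF_PANEL1=0;AF_PANEL2=0;AF_PANEL3=0;AC_CTRL=0;AN_CTRL=604;VQSLOD=8	GT:DP	0/1:50	0/1:50	0/1:50	0/0:50	0/1:50	0/1:50	0/0:50	0/0:50
1	1410000	.	C	T	.	PASS	GENE=G1X0014;EFF=other;AF_PANEL1=0;AF_PANEL2=0;AF_PANEL3=0;AC_CTRL=0;AN_CTRL=604;VQSLOD=8	GT:DP	0/1:50	0/1:50	0/1:50	0/0:50	0/1:50	0/1:50	0/0:50	0/0:50
1	1420000	.	C	T	.	PASS	GENE=G1X0014;EFF=missense;AF_PANEL1=0;AF_PANEL2=0;AF_PANEL3=0;AC_CTRL=0;AN_CTRL=604;VQSLOD=8	GT:DP	0/1:50	./.:50	0/1:50	0/0:50	0/1:50	0/1:50	0/0:50	0/0:50
1	1430000	.	C	T	.	PASS	GENE=G1X0014;EFF=missense;AF_PANEL1=0;AF_PANEL2=0;AF_PANEL3=0;AC_CTRL=0;AN_CTRL=604;VQSLOD=8	GT:DP	0/1:50	0/0:50	0/1:50	0/0:50	0/1:50	0/1:50	0/0:50	0/0:50
1	1440000	.	C	T	.	PASS	GENE=G1X0014;EFF=missense;AF_PANEL1=0;AF_PANEL2=0;AF_PANEL3=0;AC_CTRL=0;AN_CTRL=604;VQSLOD=8	GT:DP	1/1:50	0/1:50	0/1:50	0/0:50	0/1:50	0/1:50	0/0:50	0/0:50
1	2000001	.	C	T	.	PASS	GENE=G1X0020;EFF=missense;AF_PANEL1=0;AF_PANEL2=0;AF_PANEL3=0;AC_CTRL=0;AN_CTRL=604;VQSLOD=8	GT:DP	0/1:50	0/1:50	0/1:50	0/0:50	0/1:50	0/1:50	0/0:50	0/0:50
1	2500000	.	C	T	.	PASS	GENE=G1X0024;EFF=missense;AF_PANEL1=0;AF_PANEL2=0;AF_PANEL3=0;AC_CTRL=0;AN_CTRL=604;VQSLOD=8	GT:DP	0/1:50	0/1:50	0/1:50	0/0:50	0/1:50	0/1:50	0/0:50	0/0:50
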