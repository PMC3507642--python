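# qPCR validation of twelve ChIP-seq binding sites (hg19 coordinates).
# binding_score: peak-caller (MACS) -10*log10(p) score; empty where the
# region was assayed by qPCR only.  qpcr_fold_enrichment: enrichment over
# a non-enriched gene-desert control region on chromosome 12.
chrom	start	end	binding_score	qpcr_fold_enrichment	primer_forward	primer_reverse
chr1	228856976	228857630	864.12	3.48	GAGGACACAACCCCATGACT	AGAGCGAAACTCCGTCTCAA
chr2	8808594	8809289	886.86	5.60	GATGGATGGATGGATGTCTT	CTGGTTTTCCAAGCTCACAA
chr2	237457017	237457622	633.63	8.63	GCAGGGAGGTCTTTGATCTG	TCCTGAATTGGTTTGCTCAT
chr3	187946846	187947612	665.42	8.93	CCCATTTGGCTTCTTACTTTGT	TTCCTTCCTGACTCCCACTG
chr4	175441647	175442310	986.29	23.03	CCAAAATATCATGTGCAATCAA	AAACACAATGCAAGAGGAACA
chr6	35699525	35700397		8.01	CGCATAGAAGCTAAGGGGAAAT	GATGTGAATGCAAGCCTGTC
chr6	43721200	43721909	1211.19	20.88	TGGCCTCTGTCTTTTGTGTT	CACAGCTTCCAACTAGCTTTACA
chr9	82188374	82188956	532.18	9.22	GTTGCGGGAGGAGAGTTTTA	GAAGCAGGGAGACGGAGAAA
chr10	3852210	3852832	500.44	12.13	CACCAGCTCCCAACTTTCAG	CAGCTTCCACTCCCTGTACC
chr19	51353679	51354605	3100	42.11	GTGTTGCTGTCTTTGCTCAG	CAGTGTTGGGAGGCAATTCT
chr20	35888865	35889525	511.25	3.10	GCAAGACCCCATCTCAAAGA	GGCTCGGCTACACTTCATTC
chr20	56260437	56261119	1605.03	35.60	CTGGCTGCTCCAGAGAACTA	CGGCCACGTACAGTCCTATT
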