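build	chromosome	accession
GRCh37	1	NC_000001.10
GRCh37	2	NC_000002.11
GRCh37	3	NC_000003.11
GRCh37	4	NC_000004.11
GRCh37	5	NC_000005.9
GRCh37	6	NC_000006.11
GRCh37	7	NC_000007.13
GRCh37	8	NC_000008.10
GRCh37	9	NC_000009.11
GRCh37	10	NC_000010.10
GRCh37	11	NC_000011.9
GRCh37	12	NC_000012.11
GRCh37	13	NC_000013.10
GRCh37	14	NC_000014.8
GRCh37	15	NC_000015.9
GRCh37	16	NC_000016.9
GRCh37	17	NC_000017.10
GRCh37	18	NC_000018.9
GRCh37	19	NC_000019.9
GRCh37	20	NC_000020.10
GRCh37	21	NC_000021.8
GRCh37	22	NC_000022.10
GRCh37	X	NC_000023.10
GRCh37	Y	NC_000024.9
GRCh37	MT	NC_012920.1
GRCh38	1	NC_000001.11
GRCh38	2	NC_000002.12
GRCh38	3	NC_000003.12
GRCh38	4	NC_000004.12
GRCh38	5	NC_000005.10
GRCh38	6	NC_000006.12
GRCh38	7	NC_000007.14
GRCh38	8	NC_000008.11
GRCh38	9	NC_000009.12
GRCh38	10	NC_000010.11
GRCh38	11	NC_000011.10
GRCh38	12	NC_000012.12
GRCh38	13	NC_000013.11
GRCh38	14	NC_000014.9
GRCh38	15	NC_000015.10
GRCh38	16	NC_000016.10
GRCh38	17	NC_000017.11
GRCh38	18	NC_000018.10
GRCh38	19	NC_000019.10
GRCh38	20	NC_000020.11
GRCh38	21	NC_000021.9
GRCh38	22	NC_000022.11
GRCh38	X	NC_000023.11
GRCh38	Y	NC_000024.10
GRCh38	MT	NC_012920.1
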