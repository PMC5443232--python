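strain	habitat	genome_size_bp	gc_percent	n_genes	accession
AAP1	freshwater	4750579	65.6	4304	LJHO00000000
AAP83	freshwater	4232088	59.4	4074	LJHY00000000
AAP93	freshwater	4267112	65.5	3948	LJHZ00000000
DSM19966	freshwater	3708535	64.3	3496	AUBA00000000.1
DSM12444	freshwater	4233314	65.1	4124	CP000248.1
FNE08-7	freshwater	3963850	65.4	3721	LLZS00000000.1
MBES04	marine	5361448	65.4	5202	BBNP00000000
Musc273	marine	5027021	63.4	4887	JTDI00000000
US6-1	marine	5457578	63.1	5087	CP009291
PP1Y	marine	5313905	63.3	5135	FR856862.1
DSM12447	marine	4885942	63.2	4838	ZRVC00000000.1
P6W	rhizosphere	6537300	63.7	6279	JXZE00000000
AP12	rhizosphere	5611617	65.9	5367	AKKE00000000
NBRC15208	rhizosphere	6952763	64.5	6330	BCZE01000000
LL02	contaminated_soil	5307348	64.0	5220	JACU01000000
KN65.2	contaminated_soil	5024847	63.1	5036	CCBH000000000
LE124	contaminated_soil	4857928	64.6	4749	ATHL00000000
NBRC102051	contaminated_soil	5236092	63.8	5224	BCTX00000000.1
ST904	contaminated_soil	6269463	64.5	6945	LGJH00000000
B-7		4909165	65.1	4715	APCQ00000000
Leaf2		3715735	64.1	3675	LMJY00000000
DSM13790		4148048	64.0	3867	AEWJ0000000
KF1		6304486	65.1	6079	JFYZ00000000.1
Rr2-17		4539029	62.7	4513	AKFJ00000000
NBRC16725		4291514	61.3	4223	BASZ00000000.1
NBRC12533		4836455	65.7	4452	BCYV00000000.1
NBRC107847		4407848	65.7	4266	BCTW00000000.1
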