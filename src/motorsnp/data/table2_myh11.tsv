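ID of SNP Cluster	Gene	Function	Base Change	Amino Acid Change	Peptide Sequence#
rs61734198	MYH11	missense	G -->C	Q -->H	473
	MYH11	missense	G -->T	Q -->H	473
	MYH11	missense	G -->C	Q -->H	480
	MYH11	missense	G -->T	Q -->H	480
rs16967494	MYH11	missense	G -->A	A -->T	1234
	MYH11	missense	G -->A	A -->T	1241
rs16967494	MYH11	missense	G -->A	A -->T	1234
	MYH11	missense	G -->A	A -->T	1241
rs35176378	MYH11	missense	A -->G	M -->V	1508
	MYH11	missense	A -->G	M -->V	1515
rs35035518	MYH11	missense	C -->T	S -->L	883
	MYH11	missense	C -->T	S -->L	890
rs34321232	MYH11	missense	A -->C	K -->Q	1621
	MYH11	missense	A -->C	K -->Q	1628
rs34263860	MYH11	missense	G -->A	A -->T	1104
	MYH11	missense	G -->A	A -->T	1111
rs16967510	MYH11	missense	T -->C	V -->A	1289
	MYH11	missense	T -->C	V -->A	1296
rs16967494	MYH11	missense	G -->A	A -->T	1234
	MYH11	missense	G -->A	A -->T	1241
rs12149651	MYH11	missense	C -->A	L -->M	1053
	MYH11	missense	C -->A	L -->M	1060
rs7196804	MYH11	missense	G -->A	V -->M	1310
	MYH11	missense	G -->A	V -->M	1317
rs1801902	MYH11	missense	A -->G	T -->A	864
	MYH11	missense	A -->G	T -->A	871
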