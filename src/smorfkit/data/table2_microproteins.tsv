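# Packaged reference table of 35 ribosome-occupied smORFs in 15 lncRNAs and
# their predicted microproteins (gene name, Ensembl gene id, ORF nt length,
# microprotein aa length, predicted subcellular localization + score, peptide).
# NOTE: residues 61-93 of the 93-aa MIR22HG microprotein are a SYNTHETIC
# placeholder (poly-G) completing a sequence whose published tail was not
# recoverable; all other sequences are verbatim. '-' marks absent localization.
gene_name	ensembl_gene_id	orf_nt_length	mp_aa_length	localization	localization_score	aa_sequence
CYTOR	ENSG00000222041.11	156	52	Nucleus	0.37	MTDTENHDSAPSSTSTCCPPITAGMQLKDSLGPGSNRPLWTLRPLHLRVVCL
EBLN3P	ENSG00000281649.2	141	47	Nucleus	0.77	MEEPMDTSEPLSALPFTGQQSFEPSGKFGQYPSMQMNHIQALGKWRT
EBLN3P	ENSG00000281649.2	78	26	Extracellular	0.52	MYVTDPESPAAWDPCLPSVSPAELWN
GAS5	ENSG00000234741.8	150	50	Extracellular	0.43	MVLGADAVWLWIAPYGQLCPQGRMRIATEVLKSKPNSSHWHTGIRQKAGS
GAS5	ENSG00000234741.8	81	27	Extracellular	1	MTCLGKDMKTVPVIPFKGTCFIDVNVN
LINC00968	ENSG00000246430.7	132	44	Extracellular	0.53	MFLQKLKSCLVKAFHKMVCVWDQEDRRLLKKRTGTLTHFRLLHV
LINC01116	ENSG00000163364.10	249	83	Nucleus	0.71	MGPRFLADARGRGRVPGSRFSQAPIPAHARGPRPTHEAPTPIVEAPPGKEVRLPLQAAPRGMGNRQEMTRTASLRLCSRPSLC
MEG3	ENSG00000214548.18	168	56	Nucleus	0.50	MPFERLEAKSIKHSWENTTGGTTRFSYTLGSHGEDRREKKEVEREERAGETGEENN
MEG3	ENSG00000214548.18	444	148	Nucleus/Cytoplasm	0.418/0.417	MRRLSIVMKNPWHSPHPQTHGSHSHTGPKATVSAAVAPVDIGKPGEGVEEISWPPAGSLGFCAQGSWSPKNFQKLTPHVPILLGFLDFSEAPAEGSRCSLECRGSPLTWLLESLLFLLLLPSSSSSSLSISPSLCPSPVPDLAIPGCP
MEG3	ENSG00000214548.18	252	84	Cytoplasm	0.37	MEAAEEALMGPTIPDPSLLPGGPLVSFLVWAEAITWMPTWEGTSNVGPQPLSSSKSLHSHGDTLHLFPRDRLDPETLDPGPPLE
MIR22HG	ENSG00000186594.14	279	93	Mitochondria	0.60	MGWEGPNSRVDDTFWASWRAFAQIGPARSGFRLETLAGLRSRRLKQPKRLQEAVSVRFGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGG
MIR22HG	ENSG00000186594.14	66	22	Mitochondria	0.50	MIRFGQVGEPLPRLAQQGAVLD
MSC-AS1	ENSG00000235531.10	192	64	Nucleus	0.42	MSLETTGPQERQALSVLLLPWKKPAPTMPSATSKSSLRPPQKQMLSCFLYSCRTTSNHPNTREH
SNHG1	ENSG00000255717.7	87	29	Extracellular	0.47	MSYWAPVCRIYAHVGTEESSVVAPTRAYW
SNHG1	ENSG00000255717.7	153	51	Extracellular	0.73	MFSPQELTGEGMGQDPSLCKASVTVMFQVGVHGLCSYRGDLVDNHSMMNTK
SNHG16	ENSG00000163597.15	99	33	Nucleus	0.78	MATPVGVEHGEQSQAFSDDGAVSLSFQSRKRIL
SNHG16	ENSG00000163597.15	108	36	Nucleus	0.58	MATPVGVEHGEQSQAFSDDGWLGGLKVLDEKMLSKR
SNHG29	ENSG00000175061.18	405	135	Mitochondria	0.69	MFPGSLSRGRRAAVEMAWLPGSCARVAFAAGAAARYWTAWQGSAGPNPAAVAEAHGSLFCGRATSARAWSLRRPGPGSPAHSGGVQTRENWVSWGRLAVWGTPRAVYVGKIVTVLLEDLFDCPDDTCNRKCRQKR
SNHG29	ENSG00000175061.18	285	95	Mitochondria	0.66	MFPGSLSRGRRAAVEMAWLPGSCARVAFAAGAAARYWTAWQGSAGPNPAAVAEAHGSLFCGRATSARAWSLRRPGPGSPAHSGGVQTRENWVANS
SNHG29	ENSG00000175061.18	111	37	Extracellular	0.68	MDHSFVVGPHLPEPGVCEGRDPVPRPTVGVCKPERTG
SNHG29	ENSG00000175061.18	237	79	Nucleus/Extracellular	0.243/0.230	MDHSFVVGPHLPEPGVCEGRDPVPRPTVGVCKPERTGLQIREESASCLAAEYWSQEPAMRLYSQRMSVPRTSSCHQFGF
SNHG29	ENSG00000175061.18	210	70	Endoplasmic Reticulum	0.49	MLALCIRGHAQQIQEIYLATFSRKGTLGIIHYILEFFWVFFFFFETVLLYCPGWSVVAQSQLIASSITQA
SNHG29	ENSG00000175061.18	54	18	-	-	MYQRTCSADPRDIFGNFF
SNHG29	ENSG00000175061.18	237	79	Golgi Apparatus	0.42	MLSRSKRYIWQLFLEKAHWVSFITFLSFFGFFFFFLRQSCCIAQAGVWWHNHSSLHPQSPRPKQSSHLVAGTTAHSTPG
SNHG29	ENSG00000175061.18	78	26	Mitochondria	0.97	MLPRLVSGSWAQMVLLPQLPKAQAKL
SNHG5	ENSG00000203875.12	105	35	Mitochondria	0.26	MALSSVAQWSSSEDAKIHEKTSRTSGRIFNGKSLG
SNHG5	ENSG00000203875.12	72	24	Mitochondria	0.57	MQRYTKKLPEHLGEYLMENRLVKT
SNHG6	ENSG00000245910.8	75	25	Mitochondria	0.86	MPVWWRRRRLRARSWALRGARKPLR
SNHG8	ENSG00000269893.8	156	52	Mitochondria	0.68	MIIGPKLTALPKRQRSQDIGRSGAALETLKFTSMRGLECSLGRRASTCSPGP
SNHG8	ENSG00000269893.8	108	36	Mitochondria/Nucleus	0.309/0.303	MDDGNIRLSRNPSGNGRSLFSIRQWTYRSWGNGCSE
ZFAS1	ENSG00000177410.13	75	25	Mitochondria	0.34	MDFGRGSHHWTSKEATCRHLQPSIS
ZFAS1	ENSG00000177410.13	60	20	-	-	MRVLEVEYIYTYKIETGDGI
ZFAS1	ENSG00000177410.13	99	33	Extracellular	0.44	MRVLEVEYIYTYKIGWEPRVPVCVDLGLIQSAL
ZFAS1	ENSG00000177410.13	153	51	Nucleus	0.57	MEYERSPLERKGQTLCFHESEDLAEPVPQGYCIHSLSLKGCAHFKNVIVRL
ZFAS1	ENSG00000177410.13	99	33	Extracellular	0.51	MRGALWKEKDRPCAFMKVKIWLNQFHKVTVYIA
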