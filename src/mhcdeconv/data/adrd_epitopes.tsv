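gene	disorder	peptide	allele	allele_normalized	el_rank
HNRNPA1	Frontotemporal lobe dementia/ALS	IEVIEIMTDR	HLA-A11:01	HLA-A*11:01	TOP 5.4%
HNRNPA2B1	Frontotemporal lobe dementia/ALS	ITIEIITDR	HLA-A11:01	HLA-A*11:01	TOP 3.25%
HNRNPA2B1	Frontotemporal lobe dementia/ALS	GGNFGFGDSR	HLA-A11:01	HLA-A*11:01	TOP 6.44%
MAPT	Frontotemporal lobe dementia/ALS	TPSLPTPPTR	HLA-A11:01	HLA-A*11:01	TOP 0.89%
MATR3	Frontotemporal lobe dementia/ALS	SQAFIEMTR	HLA-A11:01	HLA-A*11:01	TOP 2.67%
PFN1	Frontotemporal lobe dementia/ALS	EGVHGGLINK	HLA-A11:01	HLA-A*11:01	TOP 0.945%
PLD3	Alzheimer's disease	AFLLSLAALR	HLA-A11:01	HLA-A*11:01	TOP 5.04%
PLD3	Alzheimer's disease	SQLEAIFIR	HLA-A11:01	HLA-A*11:01	TOP 0.317%
PLD3	Alzheimer's disease	ALLNVVDNAR	HLA-A11:01	HLA-A*11:01	TOP 4.03%
SPTBN2	OTHER	LLLNLELQK	HLA-A11:01	HLA-A*11:01	TOP 0.614%
VCP	Frontotemporal lobe dementia/ALS	DVDLEFLAK	HLA-A01:01	HLA-A*01:01	TOP 2.27%
VCP	Frontotemporal lobe dementia/ALS	GDDLSTAILK	HLA-A11:01	HLA-A*11:01	TOP 4.89%
VCP	Frontotemporal lobe dementia/ALS	LEILQIHTK	HLA-A11:01	HLA-A*11:01	TOP 5.574%
VCP	Frontotemporal lobe dementia/ALS	LAGESESNLR	HLA-A01:01	HLA-A*01:01	TOP 6.83%
VPS 35	Dementia w/ Lewy Bodies/ Parkinsons	ILVGTNLVR	HLA-A11:01	HLA-A*11:01	TOP 3.22%
VPS 35	Dementia w/ Lewy Bodies/ Parkinsons	NIIIALIDR	HLA-A11:01	HLA-A*11:01	TOP 6.24%
VPS 35	Dementia w/ Lewy Bodies/ Parkinsons	AELAELPLR	HLA-A11:01	HLA-A*11:01	TOP 5.92%
TARDBP	Frontotemporal lobe dementia/ALS	FTEYETQVK	HLA-A01:01	HLA-A*01:01	TOP 1.04%
EIF4G1	Dementia w/ Lewy Bodies/ Parkinsons	TTIQMSVEESTPISR	HLA-DRB1:0101	HLA-DRB1*01:01	TOP 6.26%
FUS	Frontotemporal lobe dementia/ALS	GEATVSFDDPPSAK	HLA-DQA1:0101-DQB1:0501	HLA-DQA1*01:01-DQB1*05:01	TOP 0.12%
PARK7	Dementia w/ Lewy Bodies/ Parkinsons	GAEEMETVIPVDVMR	HLA-DQA1:0101-DQB1:0302	HLA-DQA1*01:01-DQB1*03:02	TOP 4.29%
SOD1	Frontotemporal lobe dementia/ALS	GDGPVQGIINFEQK	HLA-DRB1:0404	HLA-DRB1*04:04	TOP 0.82%
TUBA4A	Frontotemporal lobe dementia/ALS	LISQIVSSITASLR	HLA-DRB1:0404	HLA-DRB1*04:04	TOP 6.41%
TUBA4A	Frontotemporal lobe dementia/ALS	AVFVDLEPTVDEIR	HLA-DRB1:0101	HLA-DRB1*01:01	TOP 1.55%
TUBA4A	Frontotemporal lobe dementia/ALS	LISQIVSSITASLRFD	HLA-DRB1:0404	HLA-DRB1*04:04	TOP 4.32%
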