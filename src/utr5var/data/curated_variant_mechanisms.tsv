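gene	csq
SLC2A1	uStart_gain
POMC	uStart_gain
BMPR2	uStart_gain
PROS1	uStart_gain
THPO	uStop_gain
ANKH	uStart_gain
NIPBL	uStart_gain
MEF2C	uStart_gain
MEF2C	uStart_gain
MEF2C	uStart_gain
MEF2C	uStart_gain
SLC22A5	uStart_gain
TWIST1	uStart_gain
TWIST1	uStart_gain
TWIST1	uStart_gain
CFTR	uStart_gain
GRHPR	uStart_gain
ENG	uStart_gain
ENG	uStart_gain
IFITM5	uStart_gain
IFITM5	uStart_gain
PAX6	uStop_loss
PAX6	uStop_loss
RDH12	uStart_gain
SMAD6	uStart_gain
HBA2	mKozak
HBA1	mKozak
CHST6	uStart_gain
SOX9	uStart_gain
ELANE	mKozak
AVP	mKozak
AR	uStart_gain
EFNB1	uStart_gain
EFNB1	uStop_loss
IGBP1	uStop_gain
VMA21	uStart_gain
SRY	uStart_gain
PAM	promoter
MOCS2	start_loss_other_transcript
PAX6	TFBS
HNF1A	TFBS
HCFC1	TFBS
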