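# Synthetic placeholder training set (20 entries). The identities of the 20
# peroxisomal training genes behind the published search motif are not public;
# these tripeptides are a constructed stand-in whose positional unions equal
# the documented search grammar (S/A/C/E/I/H/Q)-(K/R/H)-(L/F)-stop.
# Edit or replace this file to train on real C-termini.
gene_id	tripeptide
train01	SKL
train02	AKL
train03	CKL
train04	EKL
train05	IKL
train06	HKL
train07	QKL
train08	SRL
train09	SHL
train10	SKF
train11	AKF
train12	CRL
train13	EHF
train14	IRL
train15	HRL
train16	QHF
train17	AHL
train18	CKF
train19	QRL
train20	IHF
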