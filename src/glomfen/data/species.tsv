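# 34-species macrophage / glomerular-endothelial-cell signaling network.
# provenance: 'default' = documented default parameter values; 'transcribed' = printed best-fit value.
id	ymax	y0	tau	tau_class	compartment	provenance
GLU	1.0	0.0	1.0	signaling	extracellular	default
AGE	1.0	0.0	1.0	signaling	extracellular	default
TLR4	1.0	0.0	0.35	ligand-receptor	macrophage	default
RAGE	1.0	0.0	0.35	ligand-receptor	macrophage	default
NADPH	1.0	0.0	1.0	signaling	macrophage	default
ROS	1.0	0.0	1.0	signaling	macrophage	default
NFkB	1.0	0.0	0.055	nfkb	macrophage	default
IL1R	1.0	0.0	0.35	ligand-receptor	macrophage	default
VEGFAmRNA	1.0	0.0	88.0	transcription	macrophage	default
VEGFA	1.0	0.0	1.13	translation	extracellular	default
IL6	1.0	0.0	90.0	combined-transcription-translation	extracellular	default
TNFa	1.0	0.0	90.0	combined-transcription-translation	extracellular	default
IL1b	1.0	0.0	90.0	combined-transcription-translation	extracellular	default
RAGEec	1.0	0.0	0.35	ligand-receptor	GEC	default
NADPHec	1.0	0.0	1.0	signaling	GEC	default
ROSec	1.0	0.0	1.0	signaling	GEC	default
NFkBec	1.0	0.0	0.055	nfkb	GEC	default
VEGFR1	1.0	0.0	0.35	ligand-receptor	GEC	default
VEGFR2	1.0	0.0	0.35	ligand-receptor	GEC	default
PI3K	1.0	0.0	1.0	signaling	GEC	default
AKT	1.0	0.0	1.0	signaling	GEC	default
PLCg	1.0	0.0	1.0	signaling	GEC	default
Ca	1.0	0.0	1.0	signaling	GEC	default
eNOS	1.0	0.0	1.0	signaling	GEC	default
NO	1.0	0.0	1.0	signaling	GEC	default
ONOO	1.0	0.0	1.0	signaling	GEC	default
pJunction	1.0	0.0	1.0	signaling	GEC	default
MLCK	1.0	0.0	1.0	signaling	GEC	default
MLCP	1.0	0.0	1.0	signaling	GEC	default
MLC	1.0	0.0	1.0	signaling	GEC	default
pMLC	1.0	0.0	400.0	custom	GEC	transcribed
RhoRock	1.0	0.0	1.0	signaling	GEC	default
Actin_s	1.0	0.0	1.0	signaling	GEC	default
Actin_r	1.0	0.0	1.0	signaling	GEC	default
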