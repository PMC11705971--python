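term	category	symbol	system
major capsid protein	structural	MCP
hk97	structural	MCP
capsid	structural	MCP
head maturation protease	structural	prohead_protease
portal protein	structural	portal
portal	structural	portal
adaptor	structural	adaptor
minor tail protein	structural	minor_tail
tail assembly chaperone	structural	tac
tail completion protein	structural	tcp
tape measure	structural	TMP
tail fiber	structural	tail_fiber
baseplate	structural	baseplate
terminase large subunit	structural	terL
terminase small subunit	structural	terS
terminase	structural	terL
dna polymerase	replication	polA
minichromosome maintenance	replication	MCM
mcm	replication	MCM
dna primase	replication	priS
primase-polymerase	replication	primpol
primpol	replication	primpol
primase	replication	priS
dead/deah box helicase	replication	deaD
deah	replication	deaD
helicase	replication	deaD
sliding clamp	replication	PCNA
holliday junction resolvase	replication	hjr
hera	replication	herA
trmb	replication	trmB
sigma factor	replication	rpoN
rna polymerase	replication	rpo
ribonucleotide reductase	replication	nrd
thymidylate synthase	replication	thyX
integrase	mobilization	int
recombinase	mobilization	xerC
transposase	mobilization	tnp
excisionase	mobilization	xis
drma	defense	DrmA	DISARM
drmb	defense	DrmB	DISARM
drmc	defense	DrmC	DISARM
drmd	defense	DrmD	DISARM
drme	defense	DrmE	DISARM
mtase_ii	defense	MTase_II	DISARM
mtase	defense	MTase_II	DISARM
pbea	defense	PbeA	Dnd
pbec	defense	PbeC	Dnd
dnda	defense	DndA	Dnd
dndb	defense	DndB	Dnd
dndc	defense	DndC	Dnd
dndd	defense	DndD	Dnd
dnde	defense	DndE	Dnd
paris	defense	AriA	PARIS
aria	defense	AriA	PARIS
arib	defense	AriB	PARIS
hmaa	defense	HmaA	HMA
hmab	defense	HmaB	HMA
hmac	defense	HmaC	HMA
ppiwi	defense	pPIWI	pAgo
piwi	defense	pPIWI	pAgo
argonaute	defense	pPIWI	pAgo
restriction endonuclease	defense	hsdR	R-M
restriction enzyme	defense	hsdR	R-M
restriction-modification	defense	hsdR	R-M
methyltransferase	defense	hsdM	R-M
methylase	defense	hsdM	R-M
cas1	defense	cas1	CRISPR-Cas
cas2	defense	cas2	CRISPR-Cas
cas3	defense	cas3	CRISPR-Cas
cas4	defense	cas4	CRISPR-Cas
cas5	defense	cas5	CRISPR-Cas
cas6	defense	cas6	CRISPR-Cas
cas7	defense	cas7	CRISPR-Cas
cas8	defense	cas8	CRISPR-Cas
cas8b	defense	cas8b	CRISPR-Cas
cas9	defense	cas9	CRISPR-Cas
crispr-associated	defense	cas	CRISPR-Cas
ccda	antitoxin	CcdA
maze	antitoxin	MazE
relb	antitoxin	RelB
antitoxin	antitoxin	antitoxin
phycocyanobilin lyase	amg	cpcE
cpce	amg	cpcE
sulfite oxidase	amg	sorA
glutamate-cysteine ligase	amg	gshA
gsha	amg	gshA
tyrosine decarboxylase	amg	mfnA
mfna	amg	mfnA
udp-glucose 4-epimerase	amg	galE
holin	lysis	hol
endolysin	lysis	lys
lysozyme	lysis	lys
lysin	lysis	lys
spanin	lysis	spanin
hypothetical protein	hypothetical	hyp
unknown function	hypothetical	hyp
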