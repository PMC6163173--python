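module	n_genes	bp_term	bp_p	cc_term	cc_p	mf_term	mf_p	chromosome	chromosome_p
antiquewhite4	35	Ion transport	6e-7	Acetylcholine-gated channel complex	9e-5	Ion channel activity	2e-4
bisque4	212	Proteolysis	2e-9	Membrane raft	8e-10	Serine-type carboxypeptidase activity	3e-12	X	2e-5
black	1173	Ion transport	2e-16	Plasma membrane	5e-14	Signal transducer activity	1e-12	X	2e-13
blue	930	Regulation of cell shape	3e-25	Extrinsic component of cytoplasmic side of plasma membrane	8e-14	Protein kinase activity	1e-22	IV	1e-9
brown	933	Embryo development ending in birth or egg hatching	8e-41	Nucleus	3e-11	Protein binding	3e-8	I	1e-15
brown4	137	Embryo development ending in birth or egg hatching	8e-14	Cytoplasm	2e-15	Protein binding	7e-5	III	4e-3
coral1	153	Embryo development ending in birth or egg hatching	5e-11	Nucleus	1e-10	Protein binding	5e-2	I	3e-2
coral2	34	Body morphogenesis	2e-2	Collagen trimer	2e-25	Structural constituent of cuticle	8e-26
cyan	219	Axon guidance	2e-7	Axon	7e-3	Protein binding	3e-6	X	2e-20
darkgreen	160	Reproduction	8e-5	Cytoplasm	2e-2	Nucleotide binding	2e-4	III	1e-6
darkgrey	136	Neuropeptide signaling pathway	1e-9	Heterotrimeric G-protein complex	5e-5	Calcium ion binding	4e-4	X	2e-2
darkmagenta	109			Extracellular space	2e-4	Iron ion binding	3e-2
darkolivegreen	163	Embryo development ending in birth or egg hatching	8e-3	Nucleus	1e-2	Protein binding	6e-4	III	8e-3
darkorange	367	Embryo development ending in birth or egg hatching	2e-9	Mitochondrion	6e-4			III	2e-9
darkorange2	221	Innate immune response	4e-4					V	3e-4
darkred	167	Embryo development ending in birth or egg hatching	8e-11	P granule	8e-4			I	2e-3
darkseagreen4	41	Nematode larval development	1e-7	Mitochondrion	6e-16	NADH dehydrogenase (ubiquinone) activity	4e-7
darkslateblue	127	Endoplasmic reticulum unfolded protein response	1e-4	Collagen trimer	8e-34	Structural constituent of cuticle	9e-34
floralwhite	86			Pseudopodium	3e-3			IV	1e-4
green	602	Embryo development ending in birth or egg hatching	3e-5	Nucleolus	6e-8	RNA binding	2e-6	I	4e-2
greenyellow	389	Nonmotile primary cilium assembly	1e-29	Ciliary basal body	2e-19	G-protein coupled receptor activity	5e-11	X	7e-4
grey60	522	Embryo development ending in birth or egg hatching	8e-6	Nucleus	4e-14	Protein binding	9e-3	X	2e-18
honeydew1	44	Collagen and cuticulin-based cuticle development	6e-4	Collagen trimer	5e-24	Structural constituent of cuticle	4e-27
ivory	95	3'-UTR-mediated mRNA destabilization	2e-6	Nucleus	2e-6	mRNA 3'-UTR binding	1e-4
lavenderblush3	46			Cul3-RING ubiquitin ligase complex	4e-2			V	4e-2
lightcyan	213	Locomotion	6e-5	Axon	1e-4	Kinase activity	6e-5	X	8e-6
lightcyan1	98	Innate immune response	2e-38	Membrane raft	4e-17	Carbohydrate binding	1e-5	IV	8e-3
lightgreen	189			Striated muscle dense body	8e-5			I	3e-3
lightpink4	49	Maturation of LSU-rRNA	1e-3	Nucleolus	6e-10
lightsteelblue1	98					Zinc ion binding	3e-2
lightyellow	184							II	4e-7
magenta	592	Molting cycle, collagen and cuticulin-based cuticle	2e-17	Extracellular region	1e-9	Structural constituent of cuticle	5e-7	X	4e-12
mediumpurple3	100	Embryo development ending in birth or egg hatching	2e-15	Mitochondrion	7e-18	Threonine-type endopeptidase activity	6e-12	III	1e-2
navajowhite2	51	Proteolysis	7e-3			Carbohydrate binding	1e-10
paleturquoise	114	Lipid transport	2e-2	Extracellular region	1e-14	Structural constituent of cuticle	5e-11	X	3e-3
palevioletred3	55			Membrane	4e-2
pink	306			Endoplasmic reticulum	2e-2			III	9e-4
plum1	102	ATP hydrolysis coupled proton transport	2e-11	Mitochondrion	8e-8	Proton-transporting atpase activity, rotational mechanism	4e-10	X	1e-2
plum2	65
red	591	Regulation of cell shape	2e-11	Integral component of membrane	5e-4	Phosphoprotein phosphatase activity	2e-8	IV	8e-4
royalblue	292	Embryo development ending in birth or egg hatching	4e-39	Nucleus	2e-31	Helicase activity	1e-7	III	3e-8
saddlebrown	123	Transforming growth factor beta receptor signaling pathway	2e-3	Axon	2e-6	Protein binding	3e-5	X	1e-5
skyblue	128	Nucleosome assembly	5e-6	Nucleosome	2e-6	Protein heterodimerization activity	5e-4
skyblue3	104
thistle1	58	Reproduction	1e-4	Nucleolus	4e-2			I	1e-2
turquoise	3211	G-protein coupled receptor signaling pathway	4e-205	Integral component of membrane	6e-296	G-protein coupled olfactory receptor activity	6e-139	V	4e-99
white	131	Translation	3e-91	Ribosome	3e-122	Structural constituent of ribosome	4e-109	I	3e-3
yellowgreen	104	Ion transport	4e-5	Striated muscle dense body	1e-6	Actin binding	4e-4
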