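subfamily	species	gene_id	gene_name	genetic_evidence
a	Triticum aestivum	TraesCS5A02G468300	TaNAC2, TaNAC002-A1	VIGS
a	Triticum aestivum	TraesCS3A02G406000	TaNAC6A, TaNAC048-A1	Overexpression and VIGS
a	Triticum aestivum	TraesCS3B02G439600	TaNAC6B, TaNAC048-B1	VIGS
a	Triticum aestivum	TraesCS3D02G401200	TaNAC6D, TaNAC048-D1	VIGS
a	Triticum aestivum	TraesCS3B02G194000	TaNAC032, TaNAC160-B1	VIGS
a	Hordeum vulgare	HORVU1Hr1G063740	HvNAC6	Overexpression, VIGS, RNA interference
a	Hordeum vulgare	HORVU5Hr1G111590	HvSNAC1	Overexpression
a	Oryza sativa	Os11g0126900	ONAC122	VIGS
a	Oryza sativa	Os12g0123700	ONAC131	VIGS
a	Oryza sativa	Os01g0884300	OsNAC6, ONAC048	Overexpression
a	Arabidopsis thaliana	At1g01720	ATAF1, ANAC002	T-DNA insertion, overexpression
a	Arabidopsis thaliana	At5g08790	ATAF2, ANAC081	Overexpression
a	Arabidopsis thaliana	At1g52890	ANAC019	T-DNA insertion, overexpression
a	Arabidopsis thaliana	At3g15500	ATNAC3, ANAC055	T-DNA insertion, overexpression
a	Arabidopsis thaliana	At4G27410	ANAC072	T-DNA insertion
b	Oryza sativa	Os03g0119966	RIM1, ONAC054	Tos17 insertion, overexpression
b	Arabidopsis thaliana	At5g24590	TIP, ANAC091	Resistant Di-17 inbred line
b	Arabidopsis thaliana	At3g49530	NTL6, ANAC062	Overexpression of truncated NTL6, RNA interference
b	Arabidopsis thaliana	At4g35580	NTL9, CBNAC	T-DNA insertion
c	Triticum aestivum	TraesCS2D02G576400	TaNAC30, TaNAC031-D3-2	VIGS
d	Triticum aestivum	TraesCS5B02G054200	TaNAC21/22, TaNAC060-B1	VIGS
d	Triticum aestivum	TraesCS7A02G305200	TaNAC1, TaNAC104-A2	VIGS, ectopic overexpression
d	Oryza sativa	Os12g0610600	OMTN3, ONAC060	RNA interference
d	Arabidopsis thaliana	At5g39610	ANAC092	T-DNA insertion
e	Triticum aestivum	TraesCS3D02G398200	TaNAC35, TaNAC075-D1	VIGS
e	Oryza sativa	Os11g0154500	OsNAC111, ONAC017	Overexpression
e	Oryza sativa	Os03g0777000	ONAC066	Overexpression
h	Triticum aestivum	TraesCS5D02G111300	TaNACL-D1, TaNAC175-D1	Overexpression
unclassified	Arabidopsis thaliana	At5g64530	XND1, ANAC104	T-DNA insertion, complementation
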