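protein	interactor	domain_architecture	pathway	methods	ref	region	category	molecule_class
SYDE1	Munc18	Sec1-like domain	Presynaptic differentiation	coIP	CR3	Disordered domain	synaptogenesis	other
SYDE1	Liprin-alpha2	Coiled-coil, SAM domain	Presynaptic differentiation	coIP	CR3	Disordered domain	synaptogenesis	adaptor
SYDE1	Ruk/CIN85	SH3 domain	Control of Rho-family GTPases	pull-down	CR69	-	synaptogenesis	adaptor
SYDE1	XPO1	ImportinbetaN domain, exportin1	Nuclear export to the cytoplasm	AP-MS	CR80	NES 536-541; NES 713-728	intracellular homeostasis	other
SYDE1	ARHGAP28	RhoGAP domain	RhoGAP activity, actin filament	coIP;AP-MS	CR12	-	Rho-family modulator	other
SYDE2	PLEKHG3	DH domain, PH domain	RhoGEF activity	AP-MS	CR12	-	Rho-family modulator	other
SYDE2	Calcineurin	Ser/Thr phosphatase	Activity-dependent dendritogenesis	pull-down;ITC	CR41	232-289 (RVLSVP 235-240)	synaptogenesis	phosphatase
DmSyd1	Mtl	Small GTPase Rho	Rho-GTPase activity	pull-down	CR4	RhoGAP	Rho-family modulator	GTPase
DmSyd1	Rac1, Rac2	Small GTPase Rho	Rho-GTPase activity	pull-down	CR4	RhoGAP	Rho-family modulator	GTPase
DmSyd1	RhoA, RhoL	Small GTPase Rho	Rho-GTPase activity	pull-down	CR4	RhoGAP	Rho-family modulator	GTPase
DmSyd1	Cdc42	Small GTPase Rho	Rho-GTPase activity	pull-down	CR4	RhoGAP	Rho-family modulator	GTPase
DmSyd1	Neurexin-1	LamininG domain, Syndecan/Neurexin domain	Neurexin-1 recruitment to active zones	Y2H;coIP;FLAP	CR7;CR81	PDZ	synaptogenesis	other
DmSyd1	Bruchpilot	ELKS/CAST domain, coiled-coil	Presynaptic active zone organization	Y2H;coIP	CR82	PDZ, C-terminal	synaptogenesis	other
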