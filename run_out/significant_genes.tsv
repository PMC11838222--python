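pathway_id	gene	beta	se	wald	p	hr	ci_low	ci_high
PW0004	G00082	1.1183247482756846	0.30530178507571953	3.6630141156833487	0.0002492647969912607	3.05972409931172	1.6819338710491336	5.5661591249537485
PW0004	G00094	0.8874771436232125	0.290966071527522	3.0501052544171543	0.002287611802184395	2.4289939119697466	1.3732691287718224	4.296325680649899
PW0004	G00086	-0.7450934118318255	0.2725114335401679	-2.734173029558408	0.006253717174823356	0.47468995621047133	0.27825814780255326	0.8097896011547863
PW0004	G00093	0.7184564397278045	0.26307341189805505	2.7310112205722152	0.0063140321903804725	2.0512645153233033	1.2248789553037758	3.435185243084709
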