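panel	gene	subgroup
qs_module1	cqsA	autoinducer_synthesis
qs_module1	tdh	autoinducer_synthesis
qs_module1	luxR	group_behavior
qs_module2	lasI	autoinducer_synthesis
qs_module2	rhlI	autoinducer_synthesis
qs_module2	pqsH	autoinducer_synthesis
qs_module2	lasR	group_behavior
cobamide	cobG	aerobic
cobamide	cobF	aerobic
cobamide	cobA	aerobic
cobamide	cbiT	anaerobic
cobamide	cbiE	anaerobic
cobamide	cysG	other
cobamide	cbiB	other
cobamide	cobC	other
cobamide	cobD	other
cobamide	cobT	other
cobamide	cobS	other
cobamide	cobU	other
cobamide	cobO	other
cobamide	cobQ	other
cobamide	cobP	other
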