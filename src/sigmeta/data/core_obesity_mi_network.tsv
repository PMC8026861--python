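subject	subject_kind	object	object_kind	polarity	relation_class	ref_count	sentences
OBESITY	disease	NPPB	gene	negative	regulation	3	
OBESITY	disease	NPPA	gene	negative	regulation	4	
OBESITY	disease	IRS1	gene	negative	regulation	5	
OBESITY	disease	SMAD3	gene	negative	regulation	6	
OBESITY	disease	MIR155	gene	negative	regulation	7	
OBESITY	disease	ADRB1	gene	negative	regulation	3	
OBESITY	disease	AVP	gene	negative	regulation	4	
OBESITY	disease	MAPK14	gene	negative	regulation	5	
OBESITY	disease	MC3R	gene	negative	regulation	6	
OBESITY	disease	ROCK1	gene	negative	regulation	7	
OBESITY	disease	COL3A1	gene	negative	regulation	3	
NPPB	gene	MI	disease	positive	regulation	5	
NPPA	gene	MI	disease	positive	regulation	6	
IRS1	gene	MI	disease	positive	regulation	7	
SMAD3	gene	MI	disease	positive	regulation	3	
MIR155	gene	MI	disease	positive	regulation	4	
ADRB1	gene	MI	disease	positive	regulation	5	
AVP	gene	MI	disease	positive	regulation	6	
MAPK14	gene	MI	disease	positive	regulation	7	
MC3R	gene	MI	disease	positive	regulation	3	
ROCK1	gene	MI	disease	positive	regulation	4	
COL3A1	gene	MI	disease	positive	regulation	5	
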